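"""Independent oracles shared across tests.

Random Boolean rules are built as plain nested tuples — ("gene", id),
("and", [..]), ("or", [..]) — and evaluated by direct recursion, entirely
outside the package's GeneRule machinery, so truth-table comparisons are a
genuine dual route.
"""

from __future__ import annotations

import itertools
import random
from typing import Iterable, List, Set, Tuple


def random_rule_tree(rng: random.Random, gene_pool: List[str], max_depth: int):
    if max_depth <= 0 or rng.random() < 0.4:
        return ("gene", rng.choice(gene_pool))
    op = rng.choice(("and", "or"))
    n = rng.randint(2, 3)
    return (op, [random_rule_tree(rng, gene_pool, max_depth - 1) for _ in range(n)])


def tree_to_text(tree) -> str:
    """Fully parenthesized GPR text for the tuple tree."""
    kind = tree[0]
    if kind == "gene":
        return tree[1]
    inner = f" {kind} ".join(tree_to_text(c) for c in tree[1])
    return f"({inner})"


def eval_tree(tree, present: Set[str]) -> bool:
    kind = tree[0]
    if kind == "gene":
        return tree[1] in present
    results = (eval_tree(c, present) for c in tree[1])
    return all(results) if kind == "and" else any(results)


def tree_genes(tree) -> Set[str]:
    if tree[0] == "gene":
        return {tree[1]}
    out: Set[str] = set()
    for child in tree[1]:
        out |= tree_genes(child)
    return out


def all_assignments(genes: Iterable[str]):
    genes = sorted(genes)
    for bits in itertools.product((False, True), repeat=len(genes)):
        yield {g for g, b in zip(genes, bits) if b}
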