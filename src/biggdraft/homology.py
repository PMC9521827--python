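"""Bidirectional similarity search, hit filtering and reciprocal orthology.

Homologous gene pairs between a query proteome and a template proteome are
identified as reciprocal best hits (RBH): a pair (template gene *t*, query
gene *q*) is accepted iff *t* is the top-scoring subject for *q* in the
forward search and *q* is the top-scoring subject for *t* in the reverse
search, after filtering both directions on e-value, bit score and query
coverage (defaults 1e-20 / 50 / 0.75).

The search itself is an injection point (:class:`SearchEngine`): the
:class:`BlastEngine` adapter shells out to ``blastp``, while
:class:`ExactMatchEngine` and :class:`KmerEngine` are deterministic in-process
engines suitable for tests and synthetic data.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Protocol, Set, Tuple

__all__ = [
    "HomologyHit",
    "SearchParams",
    "OrthologMap",
    "EngineError",
    "SearchEngine",
    "ExactMatchEngine",
    "KmerEngine",
    "BlastEngine",
    "filter_hits",
    "collapse_hsps",
    "best_hit_per_query",
    "reciprocal_matches",
    "run_bidirectional_search",
    "build_ortholog_map",
]


@dataclass(frozen=True)
class HomologyHit:
    """One alignment (single HSP) between a query and a subject protein."""

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    evalue: float
    bitscore: float
    query_length: int

    def __post_init__(self) -> None:
        if self.aln_length <= 0:
            raise ValueError(f"aln_length must be positive, got {self.aln_length}")
        if self.query_length <= 0:
            raise ValueError(f"query_length must be positive, got {self.query_length}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")

    @property
    def query_coverage(self) -> float:
        """Alignment length over query sequence length."""
        return self.aln_length / self.query_length


@dataclass(frozen=True)
class SearchParams:
    """Thresholds and scoring settings for the similarity search.

    Defaults are the reconstruction settings used throughout this package:
    e-value <= 1e-20, bit score >= 50 (inclusive floor) and query coverage
    >= 0.75, with BLOSUM62 scoring for the external aligner.
    """

    max_evalue: float = 1e-20
    min_bitscore: float = 50.0
    min_query_coverage: float = 0.75
    scoring_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if not (0 < self.min_query_coverage <= 1):
            raise ValueError("min_query_coverage must be in (0, 1]")


class EngineError(RuntimeError):
    """A search engine failed; carries the engine's diagnostics."""


class SearchEngine(Protocol):
    """Contract for pluggable similarity-search back ends."""

    def search(
        self,
        queries: Mapping[str, str],
        subjects: Mapping[str, str],
        params: SearchParams,
    ) -> List[HomologyHit]:
        """Return unfiltered hits of ``queries`` against ``subjects``."""
        ...


def filter_hits(hits: Iterable[HomologyHit], params: SearchParams) -> List[HomologyHit]:
    """Keep hits passing all three thresholds; input order preserved."""
    return [
        h
        for h in hits
        if h.evalue <= params.max_evalue
        and h.bitscore >= params.min_bitscore
        and h.query_coverage >= params.min_query_coverage
    ]


def _hit_rank(hit: HomologyHit) -> Tuple[float, float, str]:
    # larger bitscore first, then smaller evalue, then lexicographic subject
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def collapse_hsps(hits: Iterable[HomologyHit]) -> List[HomologyHit]:
    """Keep only the top-ranked HSP per (query, subject) pair."""
    best: Dict[Tuple[str, str], HomologyHit] = {}
    order: List[Tuple[str, str]] = []
    for hit in hits:
        key = (hit.query_id, hit.subject_id)
        if key not in best:
            best[key] = hit
            order.append(key)
        elif _hit_rank(hit) < _hit_rank(best[key]):
            best[key] = hit
    return [best[k] for k in order]


def best_hit_per_query(hits: Iterable[HomologyHit]) -> Dict[str, str]:
    """Per query, the subject with maximal bit score.

    Ties broken by smaller e-value, then lexicographically smaller subject id.
    Hits are expected to be filtered and HSP-collapsed already.
    """
    best: Dict[str, HomologyHit] = {}
    for hit in hits:
        incumbent = best.get(hit.query_id)
        if incumbent is None or _hit_rank(hit) < _hit_rank(incumbent):
            best[hit.query_id] = hit
    return {q: h.subject_id for q, h in best.items()}


@dataclass(frozen=True)
class OrthologMap:
    """Reciprocal template-gene <-> query-gene pairs.

    ``pairs`` holds (template_gene_id, query_gene_id) tuples; every pair is
    reciprocal in the searches it was derived from.  The template -> query
    view is exposed as a multimap because the any-reciprocal-hit mode (and
    pooling over templates) can associate one template gene with several
    query genes.
    """

    pairs: FrozenSet[Tuple[str, str]]

    def as_multimap(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = defaultdict(set)
        for t, q in self.pairs:
            out[t].add(q)
        return dict(out)

    def query_genes(self) -> Set[str]:
        return {q for _, q in self.pairs}

    def template_genes(self) -> Set[str]:
        return {t for t, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in self.pairs


def reciprocal_matches(
    forward: Mapping[str, str], reverse: Mapping[str, str]
) -> OrthologMap:
    """Reciprocal best hits from the two directions' best-hit maps.

    ``forward`` maps query -> best template subject; ``reverse`` maps
    template -> best query subject.  A pair (t, q) is included iff
    ``forward[q] == t`` and ``reverse[t] == q``.
    """
    pairs = {
        (t, q)
        for q, t in forward.items()
        if reverse.get(t) == q
    }
    return OrthologMap(pairs=frozenset(pairs))


def _any_reciprocal(
    forward_hits: Iterable[HomologyHit], reverse_hits: Iterable[HomologyHit]
) -> OrthologMap:
    fwd = {(h.subject_id, h.query_id) for h in forward_hits}  # (template, query)
    rev = {(h.query_id, h.subject_id) for h in reverse_hits}
    return OrthologMap(pairs=frozenset(fwd & rev))


def _sequences(proteome: Mapping[str, object]) -> Dict[str, str]:
    """Accept id -> sequence strings or id -> Gene-like objects."""
    out: Dict[str, str] = {}
    for gid, value in proteome.items():
        seq = getattr(value, "protein_sequence", value)
        if not isinstance(seq, str) or not seq:
            raise ValueError(f"gene {gid!r} has no protein sequence")
        out[gid] = seq
    return out


class ExactMatchEngine:
    """Deterministic engine reporting full-length hits between identical
    sequences only.  Intended for tests and self-recovery checks."""

    def search(
        self,
        queries: Mapping[str, str],
        subjects: Mapping[str, str],
        params: SearchParams,
    ) -> List[HomologyHit]:
        by_seq: Dict[str, List[str]] = defaultdict(list)
        for sid, seq in _sequences(subjects).items():
            by_seq[seq].append(sid)
        hits: List[HomologyHit] = []
        for qid, seq in _sequences(queries).items():
            for sid in by_seq.get(seq, ()):
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        identity_pct=100.0,
                        aln_length=len(seq),
                        evalue=0.0,
                        bitscore=2.0 * len(seq),
                        query_length=len(seq),
                    )
                )
        return hits


class KmerEngine:
    """Deterministic shared-k-mer engine for mutated synthetic sequences.

    For each query/subject pair, query positions covered by at least one
    k-mer also present in the subject form the pseudo-alignment; the bit
    score is two per covered residue and the e-value decays geometrically
    with it.  With random sequences of >= 60 residues and the default k=12,
    spurious shared k-mers are vanishingly rare.
    """

    def __init__(self, k: int = 12):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.k = k

    def _kmers(self, seq: str) -> Set[str]:
        k = self.k
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    def search(
        self,
        queries: Mapping[str, str],
        subjects: Mapping[str, str],
        params: SearchParams,
    ) -> List[HomologyHit]:
        k = self.k
        subject_kmers = {sid: self._kmers(s) for sid, s in _sequences(subjects).items()}
        hits: List[HomologyHit] = []
        for qid, qseq in _sequences(queries).items():
            if len(qseq) < k:
                continue
            qk = [(i, qseq[i : i + k]) for i in range(len(qseq) - k + 1)]
            for sid, skmers in subject_kmers.items():
                covered: Set[int] = set()
                for i, kmer in qk:
                    if kmer in skmers:
                        covered.update(range(i, i + k))
                if not covered:
                    continue
                c = len(covered)
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        identity_pct=100.0 * c / len(qseq),
                        aln_length=c,
                        evalue=2.0 ** (-2.0 * c),
                        bitscore=2.0 * c,
                        query_length=len(qseq),
                    )
                )
        return hits


class BlastEngine:
    """Adapter invoking NCBI ``blastp`` with tabular output.

    Runs ``blastp -query Q -subject S -outfmt '6 qseqid sseqid pident length
    evalue bitscore qlen' -matrix M``.  Threshold filtering is left to
    :func:`filter_hits` so the pipeline behaves identically across engines.
    """

    def __init__(self, program: str = "blastp", extra_args: Optional[List[str]] = None):
        self.program = program
        self.extra_args = list(extra_args or [])

    def search(
        self,
        queries: Mapping[str, str],
        subjects: Mapping[str, str],
        params: SearchParams,
    ) -> List[HomologyHit]:
        if shutil.which(self.program) is None:
            raise EngineError(f"aligner executable not found: {self.program!r}")
        qseqs, sseqs = _sequences(queries), _sequences(subjects)
        with tempfile.TemporaryDirectory(prefix="biggdraft_blast_") as tmp:
            qpath = Path(tmp) / "query.faa"
            spath = Path(tmp) / "subject.faa"
            for path, seqs in ((qpath, qseqs), (spath, sseqs)):
                with open(path, "w") as fh:
                    for gid, seq in seqs.items():
                        fh.write(f">{gid}\n{seq}\n")
            cmd = [
                self.program,
                "-query", str(qpath),
                "-subject", str(spath),
                "-outfmt", "6 qseqid sseqid pident length evalue bitscore qlen",
                "-matrix", params.scoring_matrix,
            ] + self.extra_args
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise EngineError(
                    f"{self.program} failed (exit {proc.returncode}): {proc.stderr.strip()}"
                )
        hits: List[HomologyHit] = []
        for line in proc.stdout.splitlines():
            if not line.strip():
                continue
            q, s, pident, length, evalue, bits, qlen = line.split("\t")
            hits.append(
                HomologyHit(
                    query_id=q,
                    subject_id=s,
                    identity_pct=float(pident),
                    aln_length=int(length),
                    evalue=float(evalue),
                    bitscore=float(bits),
                    query_length=int(qlen),
                )
            )
        return hits


def run_bidirectional_search(
    query_proteome: Mapping[str, object],
    template_proteome: Mapping[str, object],
    params: SearchParams,
    engine: SearchEngine,
) -> Tuple[List[HomologyHit], List[HomologyHit]]:
    """Run the forward (query vs template) and reverse (template vs query)
    searches and filter both with :func:`filter_hits`."""
    if not query_proteome:
        raise ValueError("query proteome is empty")
    if not template_proteome:
        raise ValueError("template proteome is empty")
    qseqs = _sequences(query_proteome)
    tseqs = _sequences(template_proteome)
    forward = filter_hits(engine.search(qseqs, tseqs, params), params)
    reverse = filter_hits(engine.search(tseqs, qseqs, params), params)
    return forward, reverse


def build_ortholog_map(
    query_proteome: Mapping[str, object],
    template_proteome: Mapping[str, object],
    params: SearchParams,
    engine: SearchEngine,
    mode: str = "best",
) -> OrthologMap:
    """Full pipeline: bidirectional search -> HSP collapse -> reciprocity.

    ``mode='best'`` is reciprocal best hit with deterministic tiebreaks;
    ``mode='any'`` accepts any pair hit in both directions after filtering
    (a looser setting for sensitivity analysis).
    """
    forward, reverse = run_bidirectional_search(
        query_proteome, template_proteome, params, engine
    )
    forward = collapse_hsps(forward)
    reverse = collapse_hsps(reverse)
    if mode == "best":
        omap = reciprocal_matches(best_hit_per_query(forward), best_hit_per_query(reverse))
    elif mode == "any":
        omap = _any_reciprocal(forward, reverse)
    else:
        raise ValueError(f"unknown reciprocity mode {mode!r}")
    if mode == "best":
        fwd_best = best_hit_per_query(forward)
        rev_best = best_hit_per_query(reverse)
        for t, q in omap.pairs:  # reciprocity asserted on output
            assert fwd_best.get(q) == t and rev_best.get(t) == q
    return omap
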