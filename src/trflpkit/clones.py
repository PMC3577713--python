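"""Clone-library dereplication and diversity statistics.

16S rDNA clone sequences are trimmed to a fixed read length downstream
of the forward primer, dereplicated into ribotype groups at a 97%
pairwise-identity cutoff, and summarized by observed richness, the
Chao1 estimator (with log-normal 95% CI) and the Shannon-Weaver index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import SequenceRecord

__all__ = [
    "RibotypeGroup",
    "LibrarySummary",
    "TrimReport",
    "PRIMER_63F",
    "trim_sequences",
    "pairwise_identity",
    "dereplicate",
    "dereplicate_complete_linkage",
    "chao1",
    "shannon",
    "dominant_ribotype_fraction",
    "composition_table",
    "summarize_library",
    "GreedyDereplicator",
]

# 63F universal bacterial forward primer (Marchesi et al. 1998)
PRIMER_63F = "CAGGCCTAACACATGCAAGTC"


@dataclass(frozen=True)
class RibotypeGroup:
    """A 97%-identity sequence cluster within one library."""

    group_id: int
    seed_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.seed_id not in self.member_ids:
            raise ValueError("seed must be one of the members")

    @property
    def abundance(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class LibrarySummary:
    library_id: str
    n_clones: int
    s_obs: int
    chao1: float
    chao1_ci: tuple[float, float]
    shannon: float


@dataclass(frozen=True)
class TrimReport:
    """Sequences excluded (no primer) or kept short (< target length)."""

    excluded_ids: tuple[str, ...] = ()
    short_ids: tuple[str, ...] = ()


def _best_primer_position(
    residues: str, primer: str, max_mismatch: int = 2
) -> int | None:
    """First position of the best primer match with <= max_mismatch."""
    exact = residues.find(primer)
    if exact >= 0:
        return exact
    lp = len(primer)
    best_pos, best_mm = None, max_mismatch + 1
    for i in range(len(residues) - lp + 1):
        mm = sum(1 for a, b in zip(residues[i : i + lp], primer) if a != b)
        if mm < best_mm:
            best_mm, best_pos = mm, i
            if mm == 0:
                break
    return best_pos if best_mm <= max_mismatch else None


def trim_sequences(
    seqs: list[SequenceRecord],
    primer: str = PRIMER_63F,
    length: int = 750,
    max_mismatch: int = 2,
) -> tuple[list[SequenceRecord], TrimReport]:
    """Trim each sequence to ``length`` residues from the primer's 5' end.

    The primer is located by exact match first, then by the best
    sliding-window match with at most ``max_mismatch`` substitutions.
    Sequences with no locatable primer are excluded and reported;
    sequences shorter than ``length`` downstream of the primer are kept
    at available length and flagged.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    primer = primer.upper()
    kept: list[SequenceRecord] = []
    excluded: list[str] = []
    short: list[str] = []
    for rec in seqs:
        pos = _best_primer_position(rec.residues, primer, max_mismatch)
        if pos is None:
            excluded.append(rec.seq_id)
            continue
        trimmed = rec.residues[pos : pos + length]
        if len(trimmed) < length:
            short.append(rec.seq_id)
        kept.append(SequenceRecord(rec.seq_id, trimmed, rec.library_id))
    return kept, TrimReport(tuple(excluded), tuple(short))


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def alignment_score(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Optimal global alignment score under the package's scoring scheme
    (+1 match, -1 mismatch, -2 gap open, -1 gap extend)."""
    aligner = aligner or _DEFAULT_ALIGNER
    return float(aligner.score(a, b))


def pairwise_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Global-alignment identity, excluding terminal gap columns.

    Identity = matching columns / alignment columns between the first
    and last column where both sequences have a residue, so partial
    length clones are not penalized for overhangs.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    if sa == sb:
        return 1.0
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    cols = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    if not cols:
        return 0.0
    start, end = cols[0], cols[-1]
    span = range(start, end + 1)
    matches = sum(1 for i in span if ga[i] == gb[i] and ga[i] != "-")
    return matches / len(span)


def dereplicate(
    seqs: list[SequenceRecord], cutoff: float = 0.97
) -> list[RibotypeGroup]:
    """Greedy single-pass seeded clustering in input order.

    Each sequence joins the first existing group whose seed it matches
    at >= cutoff identity, otherwise opens a new group with itself as
    seed. Deterministic given input order.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    seeds: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in seqs:
        for gi, seed in enumerate(seeds):
            if pairwise_identity(rec, seed) >= cutoff:
                members[gi].append(rec.seq_id)
                break
        else:
            seeds.append(rec)
            members.append([rec.seq_id])
    return [
        RibotypeGroup(gi, seed.seq_id, tuple(mem))
        for gi, (seed, mem) in enumerate(zip(seeds, members))
    ]


def dereplicate_complete_linkage(
    seqs: list[SequenceRecord], cutoff: float = 0.97
) -> list[RibotypeGroup]:
    """All-pairs complete-linkage alternative for sensitivity analysis.

    Clusters on 1 - identity with complete linkage cut at 1 - cutoff;
    group seeds are each cluster's first member in input order.
    """
    n = len(seqs)
    if n == 0:
        return []
    if n == 1:
        return [RibotypeGroup(0, seqs[0].seq_id, (seqs[0].seq_id,))]
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = 1.0 - pairwise_identity(seqs[i], seqs[j])
    labels = fcluster(
        linkage(squareform(dmat, checks=False), method="complete"),
        t=1.0 - cutoff,
        criterion="distance",
    )
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    # order groups by their first member's input position
    ordered = sorted(clusters.values(), key=lambda idxs: idxs[0])
    return [
        RibotypeGroup(gi, seqs[idxs[0]].seq_id, tuple(seqs[i].seq_id for i in idxs))
        for gi, idxs in enumerate(ordered)
    ]


def chao1(groups: list[RibotypeGroup]) -> tuple[float, tuple[float, float]]:
    """Chao1 richness estimate with log-normal 95% CI.

    S_est = S_obs + F1^2/(2 F2) when doubletons exist, else
    S_obs + F1(F1-1)/2; the CI follows Chao's log-normal method on the
    estimated unseen richness T = S_est - S_obs.
    """
    if not groups:
        raise ValueError("need at least one group")
    abund = np.array([g.abundance for g in groups])
    s_obs = len(abund)
    f1 = int((abund == 1).sum())
    f2 = int((abund == 2).sum())
    if f2 > 0:
        est = s_obs + f1**2 / (2 * f2)
        r = f1 / f2
        var = f2 * (0.5 * r**2 + r**3 + 0.25 * r**4)
    else:
        est = s_obs + f1 * (f1 - 1) / 2
        if f1 > 0:
            var = (
                f1 * (f1 - 1) / 2
                + f1 * (2 * f1 - 1) ** 2 / 4
                - f1**4 / (4 * est)
            )
        else:
            var = 0.0
    t = est - s_obs
    if t <= 0 or var <= 0:
        return float(est), (float(s_obs), float(est))
    k = np.exp(1.96 * np.sqrt(np.log(1 + var / t**2)))
    return float(est), (float(s_obs + t / k), float(s_obs + t * k))


def shannon(groups: list[RibotypeGroup]) -> float:
    """Shannon-Weaver diversity H = -sum p_i ln p_i (natural log)."""
    if not groups:
        raise ValueError("need at least one group")
    abund = np.array([g.abundance for g in groups], dtype=float)
    p = abund / abund.sum()
    return float(-(p * np.log(p)).sum())


def dominant_ribotype_fraction(groups: list[RibotypeGroup]) -> float:
    """Share of the largest ribotype group, as a percentage of clones."""
    if not groups:
        raise ValueError("need at least one group")
    abund = np.array([g.abundance for g in groups])
    return float(100.0 * abund.max() / abund.sum())


def composition_table(
    groups: list[RibotypeGroup], taxon_labels: dict[int, str]
) -> dict[str, float]:
    """Percentage of clones per externally supplied taxon label.

    Every group must be labelled; the resulting percentages sum to 100.
    """
    missing = [g.group_id for g in groups if g.group_id not in taxon_labels]
    if missing:
        raise ValueError(f"unlabeled group id(s): {missing}")
    total = sum(g.abundance for g in groups)
    out: dict[str, float] = {}
    for g in groups:
        label = taxon_labels[g.group_id]
        out[label] = out.get(label, 0.0) + 100.0 * g.abundance / total
    return out


def summarize_library(
    library_id: str, groups: list[RibotypeGroup]
) -> LibrarySummary:
    est, ci = chao1(groups)
    return LibrarySummary(
        library_id=library_id,
        n_clones=sum(g.abundance for g in groups),
        s_obs=len(groups),
        chao1=est,
        chao1_ci=ci,
        shannon=shannon(groups),
    )


class GreedyDereplicator(BaseEstimator, ClusterMixin):
    """Sequence dereplication as a scikit-learn clusterer.

    Parameters
    ----------
    cutoff:
        Pairwise-identity threshold defining a ribotype (default 0.97).
    method:
        ``"greedy"`` single-pass seeded clustering (the default,
        order-dependent like the classical dereplication tools) or
        ``"complete"`` all-pairs complete linkage.

    Attributes
    ----------
    labels_ : ndarray of group indices per input sequence
    groups_ : list[RibotypeGroup]
    """

    def __init__(self, cutoff: float = 0.97, method: str = "greedy"):
        self.cutoff = cutoff
        self.method = method

    def fit(self, X: list[SequenceRecord], y=None) -> "GreedyDereplicator":
        if self.method == "greedy":
            self.groups_ = dereplicate(X, self.cutoff)
        elif self.method == "complete":
            self.groups_ = dereplicate_complete_linkage(X, self.cutoff)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        by_id = {
            sid: g.group_id for g in self.groups_ for sid in g.member_ids
        }
        self.labels_ = np.array([by_id[rec.seq_id] for rec in X])
        return self

    def fit_predict(self, X: list[SequenceRecord], y=None) -> np.ndarray:
        return self.fit(X).labels_
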