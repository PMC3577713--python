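"""Synthetic communities, peak tables and clone libraries.

The generator emulates the statistical structure of a host-associated
bacterial community survey: communities dominated by a single ribotype
with rare associates, duplicate capillary runs with size-call jitter
and fluorescence noise, a transient regime shift in which the dominant
ribotype is replaced by a different one, and clone libraries sampled
multinomially with sub-percent within-ribotype sequence
microheterogeneity. Every stage of the analysis pipeline is therefore
exercisable at desk scale with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .digest import BUILTIN_ENZYMES, Enzyme, predict_trf
from .io import PeakRecord, SequenceRecord

__all__ = [
    "TaxonModel",
    "ScenarioConfig",
    "simulate_taxa",
    "regime_abundances",
    "simulate_peak_tables",
    "simulate_clone_library",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TaxonModel:
    """A synthetic ribotype: reference 16S sequence + true TRFs."""

    taxon_id: str
    reference_seq: str
    true_trf: dict[str, int | None]  # per enzyme; None = no cut site
    mean_rel_abundance: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-design and noise parameters of a synthetic survey.

    The defaults mirror the emulated study design: 3 sites sampled over
    8 seasons with 3 colonies per sampling, a community dominated by
    one ribotype (expected share ``dominance``) with rare associates,
    duplicate runs with 0.15 bp size-call jitter, one shift season in
    which a different ribotype takes over, and 176-clone libraries with
    <1% within-ribotype divergence.
    """

    n_sites: int = 3
    n_seasons: int = 8
    colonies_per_sample: int = 3
    dominance: float = 0.7
    n_rare_taxa: int = 6
    jitter_sd: float = 0.15
    area_lognormal_sd: float = 0.5
    background_peak_rate: float = 2.0
    shift_seasons: frozenset[int] = frozenset({1})
    shift_dominant: str = "taxon_01"
    clone_library_size: int = 176
    within_ribotype_divergence: float = 0.01
    seed: int = 0
    # generator details
    enzymes: tuple[str, ...] = ("CfoI", "MspI")
    dirichlet_concentration: float = 50.0
    mean_total_fluorescence: float = 50000.0
    detection_limit: float = 300.0  # absolute fluorescence call floor
    ref_length: tuple[int, int] = (900, 1100)
    rare_overlap: float = 0.1
    include_undetectable_taxon: bool = False
    size_min: float = 80.0
    size_max: float = 600.0

    def __post_init__(self) -> None:
        if not 0 < self.dominance < 1:
            raise ValueError("dominance must be in (0, 1)")
        for name in (
            "jitter_sd",
            "area_lognormal_sd",
            "background_peak_rate",
            "within_ribotype_divergence",
            "rare_overlap",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s >= self.n_seasons for s in self.shift_seasons):
            raise ValueError("shift_seasons must index existing seasons")

    @property
    def n_taxa(self) -> int:
        return 2 + self.n_rare_taxa + int(self.include_undetectable_taxon)


def _destroy_early_sites(
    seq: np.ndarray,
    enzymes: list[Enzyme],
    keep: dict[str, int | None],
    rng: np.random.Generator,
    max_iter: int = 200,
) -> np.ndarray:
    """Mutate bases until no enzyme has a site before its planted one."""
    s = seq.copy()
    for _ in range(max_iter):
        clean = True
        text = "".join(s)
        for enz in enzymes:
            keep_pos = keep.get(enz.name)
            limit = keep_pos if keep_pos is not None else len(text)
            pos = enz.first_site(text)
            if pos is not None and pos < limit:
                # break the accidental site at a random internal base
                idx = pos + int(rng.integers(len(enz.recognition)))
                choices = [b for b in "ACGT" if b != s[idx]]
                s[idx] = choices[int(rng.integers(len(choices)))]
                clean = False
                break
        if clean:
            return s
    raise RuntimeError("could not clear accidental restriction sites")


def _plant_site(seq: np.ndarray, enzyme: Enzyme, trf: int) -> None:
    """Write a concrete recognition site so the first cut gives ``trf``."""
    start = trf - enzyme.cut_offset
    concrete = "".join(IUPAC_CONCRETE[c] for c in enzyme.recognition)
    seq[start : start + len(concrete)] = list(concrete)


IUPAC_CONCRETE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "A", "Y": "C", "S": "C", "W": "A",
    "K": "G", "M": "A", "B": "C", "D": "A",
    "H": "A", "V": "A", "N": "A",
}


def _build_reference(
    rng: np.random.Generator,
    length: int,
    enzymes: list[Enzyme],
    trfs: dict[str, int],
    max_attempts: int = 50,
) -> str:
    """Random sequence whose FIRST site of each enzyme yields its TRF."""
    keep = {enz.name: trfs[enz.name] - enz.cut_offset for enz in enzymes}
    for _ in range(max_attempts):
        seq = rng.choice(BASES, size=length)
        for enz in enzymes:
            _plant_site(seq, enz, trfs[enz.name])
        try:
            seq = _destroy_early_sites(seq, enzymes, keep, rng)
        except RuntimeError:
            continue
        for enz in enzymes:
            _plant_site(seq, enz, trfs[enz.name])
        text = "".join(seq)
        if all(enz.first_site(text) == keep[enz.name] for enz in enzymes):
            return text
    raise RuntimeError("could not build a reference with the planted sites")


def _pick_trfs(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    min_gap: int = 2,
    cross_gap: dict[str, list[int]] | None = None,
) -> list[int]:
    """Distinct integer TRFs >= min_gap apart within (lo, hi)."""
    chosen: list[int] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 10000:
            raise ValueError("too many taxa for the TRF window")
        cand = int(rng.integers(lo + 2, hi - 2))
        if all(abs(cand - c) >= min_gap for c in chosen):
            chosen.append(cand)
    return chosen


def simulate_taxa(config: ScenarioConfig) -> list[TaxonModel]:
    """Reference sequences with planted first restriction sites.

    Taxon 0 is the baseline dominant ribotype, taxon 1 the shift-regime
    dominant, the rest are rare associates. TRFs are distinct, >= 2 bp
    apart and inside the detection window; sequences are mutually
    unrelated (random), so between-taxon identity is far below the 97%
    ribotype cutoff. With ``include_undetectable_taxon`` a final taxon
    carries its first CfoI site at 636 bp, beyond the detection gate.
    """
    rng = np.random.default_rng([config.seed, 0])
    enzymes = [BUILTIN_ENZYMES[e] for e in config.enzymes]
    n_regular = 2 + config.n_rare_taxa
    lo = int(config.size_min)
    # a planted site must fit inside the shortest reference
    hi = min(int(config.size_max), config.ref_length[0] - 8)
    if hi - lo < 4 * n_regular:
        raise ValueError("TRF window too narrow for the requested taxa")

    per_enzyme_trfs: dict[str, list[int]] = {}
    for enz in enzymes:
        per_enzyme_trfs[enz.name] = _pick_trfs(rng, n_regular, lo + 4, hi - 4)

    taxa: list[TaxonModel] = []
    for t in range(n_regular):
        length = int(rng.integers(config.ref_length[0], config.ref_length[1] + 1))
        trfs = {enz.name: per_enzyme_trfs[enz.name][t] for enz in enzymes}
        # ensure planted site regions do not overlap each other
        while len(enzymes) == 2 and abs(
            trfs[enzymes[0].name] - trfs[enzymes[1].name]
        ) < 8:
            trfs[enzymes[1].name] = _pick_trfs(rng, 1, lo + 4, hi - 4)[0]
        reference = _build_reference(rng, length, enzymes, trfs)
        taxa.append(
            TaxonModel(
                taxon_id=f"taxon_{t:02d}",
                reference_seq=reference,
                true_trf=dict(trfs),
                mean_rel_abundance=0.0,  # filled below
            )
        )

    if config.include_undetectable_taxon:
        length = max(700, config.ref_length[1])
        cfoi = BUILTIN_ENZYMES["CfoI"]
        mspi = BUILTIN_ENZYMES["MspI"]
        trfs = {"CfoI": 636, "MspI": _pick_trfs(rng, 1, lo + 4, hi - 4)[0]}
        reference = _build_reference(rng, length, [cfoi, mspi], trfs)
        taxa.append(
            TaxonModel(
                taxon_id=f"taxon_{n_regular:02d}",
                reference_seq=reference,
                true_trf=dict(trfs),
                mean_rel_abundance=0.0,
            )
        )

    means = regime_abundances(config, "baseline")
    taxa = [
        replace(t, mean_rel_abundance=float(means[i])) for i, t in enumerate(taxa)
    ]
    # self-consistency: planted TRFs must agree with the digest model
    for t in taxa:
        for enz in enzymes:
            pred = predict_trf(
                SequenceRecord(t.taxon_id, t.reference_seq), enz
            )
            if pred.length_bp != t.true_trf[enz.name]:
                raise RuntimeError(
                    f"planted TRF inconsistent for {t.taxon_id}/{enz.name}"
                )
    return taxa


def regime_abundances(config: ScenarioConfig, regime: str) -> np.ndarray:
    """Expected relative abundances per taxon for a regime.

    The regime's dominant taxon carries ``dominance``; its associated
    rare taxa (half of the rare pool) share most of the remainder, and
    the other regime's rares keep a small share (``rare_overlap``) so
    that they appear sporadically, as infrequently detected associates
    do in real profiles. The off-regime dominant is absent.
    """
    if regime not in ("baseline", "shift"):
        raise ValueError(f"unknown regime {regime!r}")
    n = config.n_taxa
    n_r = config.n_rare_taxa
    means = np.zeros(n)
    half = (n_r + 1) // 2
    own = list(range(2, 2 + half))
    other = list(range(2 + half, 2 + n_r))
    if regime == "shift":
        own, other = other, own
    rest = 1.0 - config.dominance
    dom_idx = 0 if regime == "baseline" else 1
    means[dom_idx] = config.dominance
    if own:
        means[own] = rest * (1.0 - config.rare_overlap) / len(own)
    if other:
        means[other] = rest * config.rare_overlap / len(other)
    if config.include_undetectable_taxon:
        # the undetectable taxon replaces part of the rare pool share
        means[n - 1] = rest * 0.1
    return means / means.sum()


def _sample_ids(config: ScenarioConfig):
    for s in range(config.n_sites):
        for j in range(config.n_seasons):
            for c in range(config.colonies_per_sample):
                yield (
                    f"site{s}.season{j:02d}.col{c}",
                    f"site{s}",
                    f"season{j:02d}",
                    j in config.shift_seasons,
                )


def simulate_peak_tables(
    taxa: list[TaxonModel], config: ScenarioConfig
) -> list[PeakRecord]:
    """Duplicate-run electropherogram peak tables for the whole survey.

    Per sample, taxon abundances are drawn from a Dirichlet centered on
    the regime means; each replicate run jitters peak sizes with
    Gaussian sd ``jitter_sd`` and draws its total fluorescence
    log-normally. Background peaks (Poisson count per sample, uniform
    sizes, fractional areas below the 1.2% threshold in expectation)
    are shared between duplicates so the percentage threshold, not the
    duplicate filter, removes them. Peaks are only recorded above an
    absolute instrument detection limit, so runs loaded with more DNA
    record more small peaks — the count/fluorescence dependence the
    variable percentage threshold exists to remove. Fully deterministic
    given the seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    records: list[PeakRecord] = []
    for sample_id, site, season, is_shift in _sample_ids(config):
        regime = "shift" if is_shift else "baseline"
        means = regime_abundances(config, regime)
        active = means > 0
        alpha = means[active] * config.dirichlet_concentration
        p = np.zeros_like(means)
        p[active] = rng.dirichlet(alpha)
        n_bg = rng.poisson(config.background_peak_rate)
        bg_sizes = rng.uniform(config.size_min + 1, config.size_max - 1, n_bg)
        bg_fracs = rng.uniform(0.002, 0.010, n_bg)
        for enzyme in config.enzymes:
            for run in (1, 2):
                total = float(
                    np.exp(
                        rng.normal(
                            np.log(config.mean_total_fluorescence),
                            config.area_lognormal_sd,
                        )
                    )
                )
                for k, taxon in enumerate(taxa):
                    trf = taxon.true_trf.get(enzyme)
                    if trf is None or p[k] <= 0:
                        continue
                    if not (config.size_min < trf < config.size_max):
                        continue  # beyond the instrument gate, never called
                    size = trf + rng.normal(0.0, config.jitter_sd)
                    area = p[k] * total
                    if area <= config.detection_limit:
                        continue  # below the instrument call floor
                    records.append(
                        PeakRecord(sample_id, site, season, run, enzyme, size, area)
                    )
                for b in range(n_bg):
                    size = bg_sizes[b] + rng.normal(0.0, config.jitter_sd)
                    if bg_fracs[b] * total <= config.detection_limit:
                        continue
                    records.append(
                        PeakRecord(
                            sample_id,
                            site,
                            season,
                            run,
                            enzyme,
                            float(size),
                            float(bg_fracs[b] * total),
                        )
                    )
    return records


def _mutate(
    residues: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return residues
    arr = np.array(list(residues))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_clone_library(
    taxa: list[TaxonModel],
    config: ScenarioConfig,
    regime: str = "baseline",
) -> list[SequenceRecord]:
    """Multinomial clone library from a regime's expected abundances.

    Clone counts per taxon are multinomial; each clone is its taxon's
    reference with i.i.d. substitutions at rate
    ``within_ribotype_divergence / 2``, so that the *pairwise*
    divergence between clones of one ribotype is about
    ``within_ribotype_divergence`` (sub-percent by default).
    Deterministic given the seed.
    """
    if config.clone_library_size < 1:
        raise ValueError("clone_library_size must be >= 1")
    rng = np.random.default_rng(
        [config.seed, 2, 0 if regime == "baseline" else 1]
    )
    means = regime_abundances(config, regime)
    counts = rng.multinomial(config.clone_library_size, means)
    rate = config.within_ribotype_divergence / 2.0
    clones: list[SequenceRecord] = []
    i = 0
    for taxon, c in zip(taxa, counts):
        for _ in range(c):
            clones.append(
                SequenceRecord(
                    f"{regime}_clone_{i:04d}",
                    _mutate(taxon.reference_seq, rate, rng),
                    library_id=regime,
                )
            )
            i += 1
    order = rng.permutation(len(clones))
    return [clones[j] for j in order]
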