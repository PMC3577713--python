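"""In-silico prediction of labeled terminal restriction fragments.

Only the 5'-labeled (forward-primer) end fragment is relevant in
T-RFLP: the predicted TRF length of a clone is the distance from the
labeled end to the enzyme's first cut site. Predictions are then
matched against observed fingerprint bins to link ribotypes to peaks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import SequenceRecord
from .trflp import BinnedMatrix

__all__ = [
    "Enzyme",
    "PredictedTRF",
    "TRFMatch",
    "CFOI",
    "MSPI",
    "BUILTIN_ENZYMES",
    "predict_trf",
    "match_predicted_to_observed",
]

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGTN",
}


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme as recognition site + cut offset.

    ``cut_offset`` is the cut position within the recognition site on
    the labeled (5'->3') strand: CfoI GCG^C has offset 3, MspI C^CGG
    has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4:
            raise ValueError("recognition site must be >= 4 bases")
        bad = set(rec) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in recognition: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError("cut_offset must lie within the recognition site")

    def matches_at(self, seq: str, pos: int) -> bool:
        """IUPAC-aware site match at 0-based position ``pos``.

        An N in the sequence only matches a recognition N (an ambiguous
        sequence base cannot be trusted to satisfy a specific code).
        """
        site = self.recognition
        if pos + len(site) > len(seq):
            return False
        for off, code in enumerate(site):
            if seq[pos + off] not in IUPAC[code]:
                return False
        return True

    @property
    def _pattern(self) -> "re.Pattern[str]":
        # character classes built from the IUPAC sets, so an N in the
        # sequence can only satisfy a recognition N
        return re.compile(
            "".join(f"[{IUPAC[c]}]" for c in self.recognition)
        )

    def first_site(self, seq: str) -> int | None:
        """0-based start of the first recognition site, scanning 5'->3'."""
        m = self._pattern.search(seq)
        return m.start() if m else None


CFOI = Enzyme("CfoI", "GCGC", 3)
MSPI = Enzyme("MspI", "CCGG", 1)
BUILTIN_ENZYMES = {"CfoI": CFOI, "MspI": MSPI}


@dataclass(frozen=True)
class PredictedTRF:
    """Predicted labeled-end fragment for one sequence and enzyme."""

    seq_id: str
    enzyme: str
    length_bp: int | None
    detectable: bool


@dataclass(frozen=True)
class TRFMatch:
    """A predicted TRF matched (or not) to an observed fingerprint bin."""

    seq_id: str
    predicted_bp: int
    observed_bin: float | None
    offset: float | None  # observed - predicted, for drift diagnosis
    tied: bool = False


def predict_trf(
    seq: SequenceRecord,
    enzyme: Enzyme,
    window: tuple[float, float] = (80.0, 600.0),
) -> PredictedTRF:
    """Predicted terminal fragment length of a 5'-labeled sequence.

    The sequence must be oriented with the labeled (forward primer) end
    first. Fragment length (1-based) = site start + cut offset; None if
    the enzyme never cuts. ``detectable`` reflects the fragment-size
    window of the instrument gate (strict bounds, matching the
    fingerprint pipeline).
    """
    pos = enzyme.first_site(seq.residues)
    if pos is None:
        return PredictedTRF(seq.seq_id, enzyme.name, None, False)
    length = pos + enzyme.cut_offset
    lo, hi = window
    return PredictedTRF(seq.seq_id, enzyme.name, length, lo < length < hi)


def match_predicted_to_observed(
    predicted: list[PredictedTRF],
    matrix: BinnedMatrix,
    tol: float = 3.0,
) -> list[TRFMatch]:
    """Map detectable predictions to the nearest observed bin within tol.

    Electrophoretic mobility makes called sizes drift from true
    fragment lengths, so a tolerance of a few bp is allowed; the signed
    offset (observed - predicted) is reported per match. A prediction
    equidistant between two bins is assigned to the smaller bin center
    and flagged as tied. Undetectable or cut-less predictions yield no
    match entry beyond an unmatched record.
    """
    enzymes = {p.enzyme for p in predicted}
    if enzymes and enzymes != {matrix.enzyme}:
        raise ValueError(
            f"enzyme mismatch: predictions {sorted(enzymes)} vs matrix {matrix.enzyme!r}"
        )
    centers = matrix.bin_centers
    out: list[TRFMatch] = []
    for p in predicted:
        if p.length_bp is None or not p.detectable:
            continue
        best: float | None = None
        best_d = tol
        tied = False
        for c in centers:
            d = abs(c - p.length_bp)
            if d > tol:
                continue
            if best is None or d < best_d - 1e-12:
                best, best_d, tied = c, d, False
            elif abs(d - best_d) <= 1e-12:
                tied = True
                best = min(best, c)
        if best is None:
            out.append(TRFMatch(p.seq_id, p.length_bp, None, None))
        else:
            out.append(
                TRFMatch(p.seq_id, p.length_bp, best, best - p.length_bp, tied)
            )
    return out


def parse_enzyme(spec: str) -> Enzyme:
    """Enzyme from a name or ``custom:<site>@<offset>`` string."""
    if spec in BUILTIN_ENZYMES:
        return BUILTIN_ENZYMES[spec]
    if spec.startswith("custom:") and "@" in spec:
        site, _, off = spec[len("custom:") :].partition("@")
        return Enzyme(f"custom:{site}@{off}", site, int(off))
    raise ValueError(
        f"unknown enzyme {spec!r}; use CfoI, MspI or custom:<site>@<offset>"
    )
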