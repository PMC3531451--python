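"""Core domain types for 2-DE microdialysate proteomics.

The objects here mirror the stages of a two-dimensional gel
electrophoresis (2-DE) workup of pooled microdialysate: a catalog of
identified proteins (:class:`ProteinEntry`), per-gel spot
quantifications (:class:`SpotRecord` / :class:`SpotTable`), MALDI peak
lists (:class:`PeakList`), and the digitized gel image itself
(:class:`GelImage` with a linear-pH / log-MW axis calibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

FUNCTIONAL_CLASSES = (
    "inflammatory",
    "transporter",
    "contractile",
    "regulatory",
    "structural",
    "metabolic",
    "other",
)

#: ppm values are parts per million of total gel intensity.
PPM_SCALE = 1_000_000.0


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class ProteinEntry:
    """One row of the identified-protein catalog.

    ``theoretical_mw`` is in kDa, ``theoretical_pi`` in pH units; both
    refer to the canonical (unprocessed, initiator-Met retained) chain.
    ``sequence`` is optional because the catalog rows carry database
    values rather than deposited sequences.
    """

    accession: str
    name: str = ""
    sequence: str | None = None
    functional_class: str = "other"
    molecular_function: str = ""
    theoretical_mw: float | None = None
    theoretical_pi: float | None = None
    matched_peptides: int | None = None
    ms_score: float | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = "".join(self.sequence.split()).upper()
            bad = sorted(set(self.sequence) - AMINO_ACIDS)
            if bad:
                raise ValidationError(
                    f"{self.accession}: non-amino-acid symbols {bad!r} in sequence"
                )
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValidationError(
                f"{self.accession}: unknown functional class {self.functional_class!r}"
            )
        if self.theoretical_mw is not None and not self.theoretical_mw > 0:
            raise ValidationError(f"{self.accession}: theoretical_mw must be > 0")
        if self.theoretical_pi is not None and not 0 < self.theoretical_pi < 14:
            raise ValidationError(f"{self.accession}: theoretical_pi must be in (0, 14)")


@dataclass
class SpotRecord:
    """One detected spot on one gel.

    ``iod_raw`` is the background-corrected integrated optical density
    (arbitrary units); ``ppm`` is the spot's share of the total spot
    intensity on the same gel, in parts per million. Either may be
    unset (``None``) depending on pipeline stage.
    """

    spot_id: str
    gel_id: str
    pi_coord: float | None = None
    mw_coord: float | None = None
    iod_raw: float | None = None
    ppm: float | None = None
    protein: str = ""

    def __post_init__(self) -> None:
        self.spot_id = str(self.spot_id)
        if self.iod_raw is not None and self.iod_raw < 0:
            raise ValidationError(f"spot {self.spot_id}: iod_raw must be >= 0")
        if self.ppm is not None and not 0 <= self.ppm <= PPM_SCALE:
            raise ValidationError(f"spot {self.spot_id}: ppm must be in [0, 1e6]")


@dataclass
class SpotTable:
    """Ordered spot records for one gel (or one stacked multi-gel file)."""

    gel_id: str
    records: list[SpotRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.spot_id in seen:
                raise ValidationError(
                    f"gel {self.gel_id}: duplicate spot_id {rec.spot_id!r}"
                )
            seen.add(rec.spot_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpotRecord]:
        return iter(self.records)

    def by_id(self) -> dict[str, SpotRecord]:
        return {rec.spot_id: rec for rec in self.records}

    def total_iod(self) -> float:
        return float(sum(r.iod_raw for r in self.records if r.iod_raw is not None))

    def ppm_closure_ok(self, rel_tol: float = 1e-6) -> bool:
        """True if populated ppm values sum to 1e6 within ``rel_tol``.

        A table holding only a published subset of a gel's spots will
        legitimately fail closure; it is enforced on the output of ppm
        normalization, not on every table.
        """
        vals = [r.ppm for r in self.records if r.ppm is not None]
        if not vals:
            return True
        return math.isclose(sum(vals), PPM_SCALE, rel_tol=rel_tol)


@dataclass
class PeakList:
    """Centroided peptide m/z values (Da), sorted ascending."""

    source_id: str
    mz_values: list[float] = field(default_factory=list)
    charge: int = 1

    def __post_init__(self) -> None:
        if any(mz <= 0 for mz in self.mz_values):
            raise ValidationError(f"{self.source_id}: m/z values must be positive")
        self.mz_values = sorted(float(mz) for mz in self.mz_values)

    def __len__(self) -> int:
        return len(self.mz_values)


@dataclass
class AxisCalibration:
    """Maps pixel indices to separation coordinates.

    Columns map linearly to pI over ``ph_range`` (linear immobilized pH
    gradient); rows map linearly to log10(MW/kDa) over ``mw_range``
    with the heaviest proteins at the top (row 0), as on an SDS-PAGE
    gradient gel.
    """

    shape: tuple[int, int]
    ph_range: tuple[float, float] = (3.0, 10.0)
    mw_range: tuple[float, float] = (10.0, 100.0)

    def col_of_pi(self, pi: float) -> float:
        lo, hi = self.ph_range
        return (pi - lo) / (hi - lo) * self.shape[1]

    def pi_of_col(self, col: float) -> float:
        lo, hi = self.ph_range
        return lo + col / self.shape[1] * (hi - lo)

    def row_of_mw(self, mw: float) -> float:
        llo, lhi = math.log10(self.mw_range[0]), math.log10(self.mw_range[1])
        # top of the gel = highest MW
        return (lhi - math.log10(mw)) / (lhi - llo) * self.shape[0]

    def mw_of_row(self, row: float) -> float:
        llo, lhi = math.log10(self.mw_range[0]), math.log10(self.mw_range[1])
        return 10 ** (lhi - row / self.shape[0] * (lhi - llo))


@dataclass
class GelImage:
    """A digitized 2-DE gel: non-negative intensity grid plus calibration."""

    pixels: np.ndarray
    bit_depth: int = 12
    calibration: AxisCalibration | None = None
    gel_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("gel image must be a 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1:
            raise ValidationError(
                f"pixel values outside [0, {2 ** self.bit_depth - 1}]"
            )
        if self.calibration is None:
            self.calibration = AxisCalibration(shape=self.pixels.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DetectedSpot:
    """A segmented spot: centroid, disjoint pixel mask and integrated OD."""

    spot_id: str
    centroid: tuple[float, float]
    pi_coord: float
    mw_coord: float
    mask: np.ndarray | None = None
    iod: float = 0.0

    def __post_init__(self) -> None:
        if self.iod < 0:
            raise ValidationError(f"spot {self.spot_id}: IOD must be >= 0")


@dataclass
class PeptideIon:
    """A tryptic peptide with its modification state and masses (Da)."""

    sequence: str
    missed_cleavages: int = 0
    fixed_mods: tuple[str, ...] = ()
    variable_mods: tuple[str, ...] = ()
    mass_mono: float = 0.0
    mass_avg: float = 0.0
    start: int = 0  # 0-based offset of the peptide in the parent chain


@dataclass
class DifferentialRecord:
    """A matched spot compared between a patient (case) gel and control.

    ``ratio`` is case_ppm / control_ppm. A control of zero with a
    positive case gives ``inf`` (a presence call); the converse gives
    0.0 (an absence call); both are flagged ``presence_absence``.
    """

    spot_id: str
    case_ppm: float
    control_ppm: float
    ratio: float
    direction: str  # "up" | "down" | "unchanged"
    passes_twofold: bool
    presence_absence: bool = False
    absent_both: bool = False
    protein: str = ""


@dataclass
class OverlapSummary:
    """Spots passing the fold filter in both of two case-control comparisons."""

    shared_ids: list[str]
    direction_pairs: dict[str, tuple[str, str]]
    n_shared: int
    n_same_direction: int
    n_opposite_direction: int

    def __post_init__(self) -> None:
        if self.n_shared != self.n_same_direction + self.n_opposite_direction:
            raise ValidationError("overlap counts are inconsistent")

    @property
    def same_direction_ids(self) -> list[str]:
        return [s for s in self.shared_ids
                if self.direction_pairs[s][0] == self.direction_pairs[s][1]]

    @property
    def opposite_direction_ids(self) -> list[str]:
        return [s for s in self.shared_ids
                if self.direction_pairs[s][0] != self.direction_pairs[s][1]]


@dataclass
class PmfResult:
    """Outcome of matching one peak list against one candidate protein."""

    accession: str
    n_matched: int
    n_observed: int
    coverage: float
    score: float
    matches: list[tuple[float, float, float]] = field(default_factory=list)
    # matches: (observed m/z, theoretical mass, error in ppm)


@dataclass
class MsmsPeptide:
    sequence: str
    score: float
    expectation: float

    def __post_init__(self) -> None:
        if self.expectation < 0:
            raise ValidationError("expectation value must be >= 0")


@dataclass
class MsmsEvidence:
    """Per-peptide MS/MS search results for one candidate protein."""

    accession: str
    peptides: list[MsmsPeptide] = field(default_factory=list)


def as_sequence(entries: Sequence[ProteinEntry] | ProteinEntry) -> list[ProteinEntry]:
    if isinstance(entries, ProteinEntry):
        return [entries]
    return list(entries)
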