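"""ppm normalization, spot matching, fold-change classification, overlap.

The quantitative comparison works on pooled gels without replicates,
so the statistic is the fold change of normalized spot intensity:
each spot's IOD is divided by the summed IOD of all spots on the same
gel and scaled to parts per million (ppm), correcting for global
staining differences between gels; a spot is called differential when
its case/control ppm ratio is at least two-fold up or down
(boundary inclusive).
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (
    FUNCTIONAL_CLASSES,
    PPM_SCALE,
    DifferentialRecord,
    OverlapSummary,
    ProteinEntry,
    SpotRecord,
    SpotTable,
)


class NormalizationError(ValueError):
    pass


def normalize_ppm(table: SpotTable) -> SpotTable:
    """ppm_i = iod_i / sum_j iod_j * 1e6 over the spots of one gel.

    Invariant: the output ppm column sums to exactly 1e6 (within
    floating tolerance), and the result is unchanged if every IOD on
    the gel is scaled by any positive constant.
    """
    total = table.total_iod()
    if total <= 0:
        raise NormalizationError(f"gel {table.gel_id}: total IOD is zero")
    records = []
    for r in table:
        if r.iod_raw is None:
            raise NormalizationError(
                f"gel {table.gel_id}: spot {r.spot_id} has no iod_raw"
            )
        records.append(
            SpotRecord(
                spot_id=r.spot_id,
                gel_id=r.gel_id,
                pi_coord=r.pi_coord,
                mw_coord=r.mw_coord,
                iod_raw=r.iod_raw,
                ppm=r.iod_raw / total * PPM_SCALE,
                protein=r.protein,
            )
        )
    return SpotTable(gel_id=table.gel_id, records=records)


MatchedPair = tuple[SpotRecord | None, SpotRecord | None]


def match_spots(
    case: SpotTable,
    control: SpotTable,
    tol: tuple[float, float] = (0.1, 0.05),
) -> list[MatchedPair]:
    """Pair spots across two gels.

    If any spot ids are shared the tables are taken as already
    matched (fixture mode) and pairing is by id. Otherwise pairing is
    mutual nearest neighbour in (pI, log10 MW), scaled by ``tol`` =
    (max ΔpI, max Δlog10 MW): two spots may pair only if their scaled
    distance is within the unit ellipse. Spots left unmatched appear
    with ``None`` on the missing side (downstream they count as ppm 0,
    a presence/absence event).
    """
    case_ids = {r.spot_id for r in case}
    control_ids = {r.spot_id for r in control}
    if case_ids & control_ids:
        control_by_id = control.by_id()
        pairs: list[MatchedPair] = [
            (r, control_by_id.get(r.spot_id)) for r in case
        ]
        pairs.extend(
            (None, r) for r in control if r.spot_id not in case_ids
        )
        return pairs

    def coords(table: SpotTable) -> np.ndarray:
        out = np.full((len(table), 2), np.nan)
        for i, r in enumerate(table):
            if r.pi_coord is not None and r.mw_coord is not None:
                out[i] = (r.pi_coord / tol[0], math.log10(r.mw_coord) / tol[1])
        return out

    a, b = coords(case), coords(control)
    if len(a) == 0 or len(b) == 0:
        return [(r, None) for r in case] + [(None, r) for r in control]
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, nn_ab = tree_b.query(a, distance_upper_bound=1.0)
    d_ba, nn_ba = tree_a.query(b, distance_upper_bound=1.0)
    pairs = []
    matched_b: set[int] = set()
    for i, r in enumerate(case):
        j = nn_ab[i]
        if np.isfinite(d_ab[i]) and j < len(b) and nn_ba[j] == i:
            pairs.append((r, control.records[j]))
            matched_b.add(int(j))
        else:
            pairs.append((r, None))
    pairs.extend(
        (None, r) for j, r in enumerate(control) if j not in matched_b
    )
    return pairs


def classify_twofold(
    pairs: list[MatchedPair], fold: float = 2.0
) -> list[DifferentialRecord]:
    """Fold-change classification of matched spots.

    ``passes_twofold`` is true when the case/control ppm ratio is at
    least ``fold`` up or down, boundary inclusive ("at least
    two-fold"). A zero (or missing) control with a positive case
    gives ratio +inf, direction up, passing, flagged as a
    presence/absence call; the converse gives ratio 0, down, passing.
    Spots absent on both sides are flagged ``absent_both`` and never
    pass. Input ordering is preserved.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    records = []
    for case_rec, control_rec in pairs:
        case_ppm = case_rec.ppm if case_rec is not None and case_rec.ppm is not None else 0.0
        control_ppm = (
            control_rec.ppm if control_rec is not None and control_rec.ppm is not None else 0.0
        )
        anchor = case_rec if case_rec is not None else control_rec
        spot_id = anchor.spot_id if anchor is not None else ""
        protein = anchor.protein if anchor is not None else ""
        absent_both = case_ppm == 0 and control_ppm == 0
        presence_absence = (case_ppm == 0) != (control_ppm == 0)
        if absent_both:
            ratio, direction, passes = math.nan, "unchanged", False
        elif control_ppm == 0:
            ratio, direction, passes = math.inf, "up", True
        else:
            ratio = case_ppm / control_ppm
            direction = "up" if ratio > 1 else ("down" if ratio < 1 else "unchanged")
            passes = ratio >= fold or ratio <= 1 / fold
        records.append(
            DifferentialRecord(
                spot_id=spot_id,
                case_ppm=case_ppm,
                control_ppm=control_ppm,
                ratio=ratio,
                direction=direction,
                passes_twofold=passes,
                presence_absence=presence_absence,
                absent_both=absent_both,
                protein=protein,
            )
        )
    return records


def passing(records: list[DifferentialRecord]) -> list[DifferentialRecord]:
    return [r for r in records if r.passes_twofold]


def overlap_analysis(
    comparison_a: list[DifferentialRecord],
    comparison_b: list[DifferentialRecord],
) -> OverlapSummary:
    """Spots passing the fold filter in both comparisons, by spot id.

    Same-direction means both up or both down in the two comparisons;
    n_shared = n_same + n_opposite by construction.
    """
    a = {r.spot_id: r for r in passing(comparison_a)}
    b = {r.spot_id: r for r in passing(comparison_b)}
    shared = sorted(a.keys() & b.keys())
    direction_pairs = {s: (a[s].direction, b[s].direction) for s in shared}
    n_same = sum(1 for s in shared if direction_pairs[s][0] == direction_pairs[s][1])
    return OverlapSummary(
        shared_ids=shared,
        direction_pairs=direction_pairs,
        n_shared=len(shared),
        n_same_direction=n_same,
        n_opposite_direction=len(shared) - n_same,
    )


def class_proportions(entries: list[ProteinEntry]) -> pd.DataFrame:
    """Counts and percentages of catalog entries per functional class.

    Percentages carry 3 significant figures in ``percent`` and an
    integer-rounded ``percent_display`` for summary output.
    """
    counts = Counter(e.functional_class for e in entries)
    total = sum(counts.values())
    rows = []
    for cls in FUNCTIONAL_CLASSES:
        if cls not in counts:
            continue
        pct = counts[cls] / total * 100.0
        rows.append({
            "functional_class": cls,
            "count": counts[cls],
            "percent": float(f"{pct:.3g}"),
            "percent_display": round(pct),
        })
    return pd.DataFrame(rows, columns=["functional_class", "count",
                                       "percent", "percent_display"])


def differential_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Tabular view of a classification (useful for reports and CSV)."""
    return pd.DataFrame([
        {
            "spot_id": r.spot_id,
            "protein": r.protein,
            "case_ppm": r.case_ppm,
            "control_ppm": r.control_ppm,
            "ratio": r.ratio,
            "direction": r.direction,
            "passes_twofold": r.passes_twofold,
            "presence_absence": r.presence_absence,
        }
        for r in records
    ])
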