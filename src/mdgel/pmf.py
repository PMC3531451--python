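"""Peptide-mass-fingerprint search and MS/MS identification criteria.

The search digests every candidate protein in silico (trypsin, up to
one missed cleavage, fixed carbamidomethyl-C, variable oxidation-M),
matches each observed peak to at most one theoretical peptide mass
within a ppm tolerance, and ranks candidates by a MOWSE-style score:
the sum over matched peptides of the negative log frequency of
theoretical peptides in that peptide's mass bin across the whole
search collection. The score is repository-defined and used for
ranking only — it is not comparable to probabilistic search-engine
scores.

The MS/MS acceptance rule is a separate filter: a protein counts as
identified when at least ``min_peptides`` of its peptides have a
score strictly over ``min_score`` and an expectation value strictly
under ``max_expect``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MsmsEvidence, PeakList, PmfResult, ProteinEntry
from .properties import digest_masses


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass
class PmfParams:
    tolerance_ppm: float = 50.0
    max_missed: int = 1
    carbamidomethyl: bool = True
    variable_oxidation: bool = True
    mass_kind: str = "mono"  # MALDI-TOF reflectron convention
    mowse_bin_da: float = 100.0


def _digests(proteins, params: PmfParams):
    out = {}
    for p in proteins:
        if not p.sequence:
            raise ValueError(f"{p.accession}: PMF search requires a sequence")
        ions = digest_masses(
            p.sequence,
            max_missed=params.max_missed,
            carbamidomethyl=params.carbamidomethyl,
            variable_oxidation=params.variable_oxidation,
            kind=params.mass_kind,
        )
        attr = "mass_mono" if params.mass_kind == "mono" else "mass_avg"
        out[p.accession] = [(getattr(i, attr), i) for i in ions]
    return out


def pmf_search(
    peaks: PeakList,
    proteins: list[ProteinEntry],
    params: PmfParams | None = None,
) -> list[PmfResult]:
    """Rank candidate proteins by peptide-mass-fingerprint match.

    Each observed peak consumes at most one theoretical peptide per
    protein: the closest mass within tolerance wins, ties broken by
    the lower peptide mass. Results are sorted by score, then matched
    count, then accession (a documented, deterministic tie-break).
    """
    params = params or PmfParams()
    if not proteins:
        raise ValueError("empty protein collection")
    if len(peaks) == 0:
        warnings.warn("empty peak list; returning empty result set")
        return []
    digests = _digests(proteins, params)

    # MOWSE-style bin frequencies over the whole search collection
    all_masses = np.array([m for ions in digests.values() for m, _ in ions])
    bins = np.floor(all_masses / params.mowse_bin_da).astype(int)
    bin_counts = pd.Series(bins).value_counts()
    total = float(len(all_masses))

    def bin_weight(mass: float) -> float:
        b = int(np.floor(mass / params.mowse_bin_da))
        freq = bin_counts.get(b, 1) / total
        return -np.log10(freq)

    results = []
    by_acc = {p.accession: p for p in proteins}
    for acc, ions in digests.items():
        masses = sorted(ions, key=lambda t: t[0])
        available = [True] * len(masses)
        mass_arr = np.array([m for m, _ in masses])
        matches = []
        covered: set[int] = set()
        for obs in peaks.mz_values:
            lim = params.tolerance_ppm * 1e-6 * obs
            lo = np.searchsorted(mass_arr, obs - lim, side="left")
            hi = np.searchsorted(mass_arr, obs + lim, side="right")
            best = None
            for k in range(lo, hi):
                if not available[k]:
                    continue
                err = abs(obs - mass_arr[k])
                # closest wins; exact ties go to the lower mass (lower k)
                if best is None or err < best[0] - 1e-12:
                    best = (err, k)
            if best is None:
                continue
            _, k = best
            available[k] = False
            theo = mass_arr[k]
            ion = masses[k][1]
            matches.append((obs, float(theo), ppm_error(obs, theo)))
            covered.update(range(ion.start, ion.start + len(ion.sequence)))
        seq_len = len(by_acc[acc].sequence)
        score = float(sum(bin_weight(theo) for _, theo, _ in matches))
        results.append(
            PmfResult(
                accession=acc,
                n_matched=len(matches),
                n_observed=len(peaks),
                coverage=len(covered) / seq_len if seq_len else 0.0,
                score=score,
                matches=matches,
            )
        )
    results.sort(key=lambda r: (-r.score, -r.n_matched, r.accession))
    return results


def theoretical_peaklist(
    protein: ProteinEntry, params: PmfParams | None = None, source_id: str | None = None
) -> PeakList:
    """The protein's exact theoretical digest masses as a peak list."""
    params = params or PmfParams()
    ions = digest_masses(
        protein.sequence,
        max_missed=params.max_missed,
        carbamidomethyl=params.carbamidomethyl,
        variable_oxidation=params.variable_oxidation,
        kind=params.mass_kind,
    )
    attr = "mass_mono" if params.mass_kind == "mono" else "mass_avg"
    return PeakList(
        source_id=source_id or protein.accession,
        mz_values=sorted({round(getattr(i, attr), 6) for i in ions}),
    )


def make_decoys(
    proteins: list[ProteinEntry], n_decoys: int = 50, seed: int = 0
) -> list[ProteinEntry]:
    """Residue-shuffled decoy sequences (composition-preserving null)."""
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n_decoys):
        template = proteins[int(rng.integers(len(proteins)))]
        seq = list(template.sequence)
        rng.shuffle(seq)
        decoys.append(
            ProteinEntry(
                accession=f"DECOY_{i:04d}",
                name=f"shuffled decoy of {template.accession}",
                sequence="".join(seq),
            )
        )
    return decoys


def apply_msms_criteria(
    evidence: MsmsEvidence,
    min_peptides: int = 3,
    min_score: float = 25.0,
    max_expect: float = 1.0,
) -> tuple[bool, dict]:
    """Identification rule on tandem-MS peptide evidence.

    A peptide qualifies when its score is strictly over ``min_score``
    and its expectation value strictly under ``max_expect``; the
    protein is identified when at least ``min_peptides`` qualify.
    Returns (identified, rationale) where the rationale lists the
    qualifying peptides.
    """
    qualifying = [
        p for p in evidence.peptides
        if p.score > min_score and p.expectation < max_expect
    ]
    identified = len(qualifying) >= min_peptides
    rationale = {
        "accession": evidence.accession,
        "n_peptides": len(evidence.peptides),
        "n_qualifying": len(qualifying),
        "qualifying": [
            {"sequence": p.sequence, "score": p.score, "expectation": p.expectation}
            for p in qualifying
        ],
        "criteria": {
            "min_peptides": min_peptides,
            "min_score": min_score,
            "max_expect": max_expect,
        },
    }
    return identified, rationale


def flag_catalog_conformance(
    entries: list[ProteinEntry],
    min_peptides: int = 3,
    min_score: float = 25.0,
) -> pd.DataFrame:
    """Flag catalog rows that do not meet the stated identification rule.

    The catalog reports only a matched-peptide count and an aggregate
    score per spot, so the check is: at least ``min_peptides`` matched
    peptides and a score strictly over ``min_score``. Non-conforming
    rows are flagged, never removed — the catalog is reported as
    published.
    """
    rows = []
    for e in entries:
        reasons = []
        if e.matched_peptides is not None and e.matched_peptides < min_peptides:
            reasons.append(f"matched_peptides {e.matched_peptides} < {min_peptides}")
        if e.ms_score is not None and e.ms_score <= min_score:
            reasons.append(f"score {e.ms_score:g} <= {min_score:g}")
        rows.append({
            "accession": e.accession,
            "name": e.name,
            "matched_peptides": e.matched_peptides,
            "ms_score": e.ms_score,
            "conforming": not reasons,
            "reasons": "; ".join(reasons),
        })
    return pd.DataFrame(rows)
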