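"""Sequence-derived physicochemical properties.

Implements the computations the identification layer rests on:

* peptide/protein mass from a packaged residue-mass table
  (monoisotopic and average), with carbamidomethyl-C (+57.02146 Da
  mono, fixed) and oxidation-M (+15.9949 Da mono, variable)
  modifications;
* isoelectric point by bisection on the Henderson–Hasselbalch net
  charge, with selectable pKa sets (EMBOSS default, Bjellqvist);
* in-silico tryptic digestion: cleave after K or R unless followed by
  P, with a configurable number of missed cleavages.

The mass and pKa constants live in ``data/mass_constants.json`` so
tests' brute-force oracles and the implementation share one source.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .model import AMINO_ACIDS, PeptideIon, ProteinEntry

CARBAMIDOMETHYL = "carbamidomethyl_c"
OXIDATION = "oxidation_m"


@lru_cache(maxsize=1)
def mass_constants() -> dict:
    """The packaged residue-mass/pKa table, parsed once."""
    path = resources.files("mdgel.data").joinpath("mass_constants.json")
    return json.loads(path.read_text(encoding="utf-8"))


def _check_sequence(seq: str) -> None:
    for i, aa in enumerate(seq):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r} at position {i}")


def peptide_mass(
    seq: str,
    kind: str = "mono",
    n_carbamidomethyl: int | None = None,
    n_oxidation: int = 0,
) -> float:
    """Neutral peptide mass in Da: residue masses + one water + mods.

    ``n_carbamidomethyl`` defaults to None meaning *unmodified*; pass
    the cysteine count (or use :func:`digest_masses`) to apply the
    fixed alkylation. ``kind`` selects monoisotopic or average masses.
    """
    if kind not in ("mono", "avg"):
        raise ValueError(f"kind must be 'mono' or 'avg', not {kind!r}")
    _check_sequence(seq)
    consts = mass_constants()
    table = consts[f"residue_{kind}"]
    mass = sum(table[aa] for aa in seq) + consts[f"water_{kind}"]
    mods = consts["modifications"]
    if n_carbamidomethyl:
        mass += n_carbamidomethyl * mods[CARBAMIDOMETHYL][kind]
    if n_oxidation:
        mass += n_oxidation * mods[OXIDATION][kind]
    return mass


def protein_mw(entry: ProteinEntry | str, kind: str = "avg") -> float:
    """Full-chain mass in kDa (initiator Met retained, no modifications).

    Average masses by default, matching how protein databases report
    the canonical-chain molecular weight.
    """
    seq = entry if isinstance(entry, str) else entry.sequence
    if not seq:
        raise ValueError("protein_mw requires a non-empty sequence")
    return peptide_mass(seq, kind=kind) / 1000.0


def net_charge(seq: str, ph: float, pka_set: str = "emboss") -> float:
    """Henderson–Hasselbalch net charge of a free peptide at ``ph``.

    Positive groups (N-terminus, H, K, R) contribute
    1/(1+10^(pH−pKa)); negative groups (C-terminus, D, E, C, Y)
    contribute −1/(1+10^(pKa−pH)).
    """
    pka = mass_constants()["pka_sets"][pka_set]
    pos = 1.0 / (1.0 + 10 ** (ph - pka["nterm"]))
    neg = 1.0 / (1.0 + 10 ** (pka["cterm"] - ph))
    for aa in seq:
        if aa in ("H", "K", "R"):
            pos += 1.0 / (1.0 + 10 ** (ph - pka[aa]))
        elif aa in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(seq: str, pka_set: str = "emboss", tol: float = 0.01) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is continuous and strictly decreasing in pH, positive
    at 0 and negative at 14, so the root exists and is unique.
    """
    _check_sequence(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cleavage_sites(seq: str) -> list[int]:
    """Positions *after* which trypsin cleaves: K/R not followed by P.

    The chain's final residue is never a site (nothing to cleave).
    """
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def tryptic_digest(seq: str, max_missed: int = 1) -> list[PeptideIon]:
    """All tryptic peptides with 0..``max_missed`` missed cleavages.

    Peptides are returned N- to C-terminal, 0-missed first, each
    annotated with its missed-cleavage count and start offset. Masses
    are left at 0; use :func:`digest_masses` for mass-annotated ions.
    """
    _check_sequence(seq)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not seq:
        return []
    bounds = [0] + cleavage_sites(seq) + [len(seq)]
    peptides = []
    for missed in range(max_missed + 1):
        for i in range(len(bounds) - 1 - missed):
            start, end = bounds[i], bounds[i + 1 + missed]
            peptides.append(
                PeptideIon(
                    sequence=seq[start:end],
                    missed_cleavages=missed,
                    start=start,
                )
            )
    return peptides


def digest_masses(
    seq: str,
    max_missed: int = 1,
    carbamidomethyl: bool = True,
    variable_oxidation: bool = True,
    max_oxidation: int = 1,
    kind: str = "mono",
) -> list[PeptideIon]:
    """Digest and annotate masses under the search modification model.

    Carbamidomethylation is fixed on every cysteine; oxidation of
    methionine is variable, expanding each Met-containing peptide into
    variants with 0..min(#M, ``max_oxidation``) oxidations.
    """
    ions = []
    for pep in tryptic_digest(seq, max_missed=max_missed):
        n_cys = pep.sequence.count("C") if carbamidomethyl else 0
        n_met = pep.sequence.count("M") if variable_oxidation else 0
        for n_ox in range(min(n_met, max_oxidation) + 1):
            fixed = ("carbamidomethyl-C",) * (1 if n_cys else 0)
            variable = ("oxidation-M",) * (1 if n_ox else 0)
            ions.append(
                PeptideIon(
                    sequence=pep.sequence,
                    missed_cleavages=pep.missed_cleavages,
                    fixed_mods=fixed,
                    variable_mods=variable,
                    mass_mono=peptide_mass(
                        pep.sequence, "mono",
                        n_carbamidomethyl=n_cys, n_oxidation=n_ox,
                    ),
                    mass_avg=peptide_mass(
                        pep.sequence, "avg",
                        n_carbamidomethyl=n_cys, n_oxidation=n_ox,
                    ),
                    start=pep.start,
                )
            )
    return ions
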