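"""Packaged fixture data: the published quantification tables and catalog.

``load_table2`` / ``load_table3`` hold the printed ppm values of the
spots that changed at least two-fold in the trapezius-myalgia (TM) and
widespread-pain (CWP) gels versus the control (CON) gel.
``load_catalog`` holds the 97-spot identified-protein catalog with
functional classes, database MW/pI, matched-peptide counts and MS
scores. ``load_myoglobin`` is the canonical human myoglobin sequence
(P02144), the one entry asserted against a database-printed mass.

Sequences for other accessions were never deposited;
:func:`synthetic_sequences_for_catalog` generates seeded random stand-in
sequences (synthetic, for exercising the identification layer only).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io import read_fasta, read_spot_tables
from .model import ProteinEntry, SpotTable

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _data_path(name: str):
    return resources.files("mdgel.data").joinpath(name)


def load_table2() -> dict[str, SpotTable]:
    """Spots >=2-fold changed in TM vs CON; keys 'TM' and 'CON'."""
    with resources.as_file(_data_path("table2_tm_con.csv")) as p:
        return read_spot_tables(p)


def load_table3() -> dict[str, SpotTable]:
    """Spots >=2-fold changed in CWP vs CON; keys 'CWP' and 'CON'."""
    with resources.as_file(_data_path("table3_cwp_con.csv")) as p:
        return read_spot_tables(p)


def load_catalog_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("table1_catalog.csv")) as p:
        return pd.read_csv(p)


def load_catalog() -> list[ProteinEntry]:
    """The 97-spot identified-protein catalog as :class:`ProteinEntry` rows."""
    df = load_catalog_frame()
    return [
        ProteinEntry(
            accession=str(r.accession),
            name=str(r.protein),
            functional_class=str(r.functional_class),
            molecular_function=str(r.molecular_function),
            theoretical_mw=float(r.mw_kda),
            theoretical_pi=float(r.pi),
            matched_peptides=int(r.matched_peptides),
            ms_score=float(r.ms_score),
        )
        for r in df.itertuples()
    ]


def load_myoglobin() -> ProteinEntry:
    """Canonical human myoglobin (P02144), 154 residues."""
    with resources.as_file(_data_path("P02144.fasta")) as p:
        return read_fasta(p)[0]


def synthetic_sequences_for_catalog(
    seed: int = 0, mean_length: int = 300
) -> list[ProteinEntry]:
    """Seeded random sequences for the catalog's unique accessions.

    Purely synthetic stand-ins (the study deposited no sequence data);
    P02144 carries its real sequence. Lengths are drawn around
    ``mean_length`` so digests have realistic peptide counts.
    """
    rng = np.random.default_rng(seed)
    myo = load_myoglobin()
    entries = []
    for acc in dict.fromkeys(e.accession for e in load_catalog()):
        if acc == myo.accession:
            entries.append(myo)
            continue
        n = int(rng.integers(mean_length // 2, mean_length * 2))
        seq = "".join(rng.choice(list(_AA), size=n))
        entries.append(ProteinEntry(accession=acc, name=f"synthetic {acc}", sequence=seq))
    return entries
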