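"""Readers and writers for the formats the pipeline touches.

Spot tables are headered, comma-delimited UTF-8 text with columns
``spot_id, gel_id, protein, pi, mw_kda, iod_raw, ppm``; unset numeric
fields are empty cells (never 0 — a 0 IOD is a meaningful value).
FASTA goes through Bio.SeqIO; MGF peak lists through pyteomics; gel
images are 16-bit TIFF/PNG containers carrying 12-bit data.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .model import (
    GelImage,
    PeakList,
    ProteinEntry,
    SpotRecord,
    SpotTable,
    ValidationError,
)

SPOT_COLUMNS = ["spot_id", "gel_id", "protein", "pi", "mw_kda", "iod_raw", "ppm"]


class LoadError(ValueError):
    """Raised when an input file cannot be parsed."""


def _opt_float(cell: str | None) -> float | None:
    if cell is None or cell.strip() == "":
        return None
    return float(cell)


def read_spot_tables(
    path: str | Path,
    delimiter: str = ",",
    require_ppm_closure: bool = False,
) -> dict[str, SpotTable]:
    """Read a spot-table CSV, returning one :class:`SpotTable` per gel.

    Row order within each gel is preserved. With
    ``require_ppm_closure`` the populated ppm column of every gel must
    sum to 1e6 (within 1e-6 relative); published excerpt tables do not
    satisfy this, so it is off by default.
    """
    path = Path(path)
    per_gel: dict[str, list[SpotRecord]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise LoadError(f"{path}: empty file (no header)")
        missing = {"spot_id", "gel_id"} - set(reader.fieldnames)
        if missing:
            raise LoadError(f"{path}: missing required columns {sorted(missing)}")
        if not ({"iod_raw", "ppm"} & set(reader.fieldnames)):
            raise LoadError(f"{path}: need at least one of 'iod_raw' or 'ppm'")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SpotRecord(
                    spot_id=row["spot_id"],
                    gel_id=row["gel_id"],
                    pi_coord=_opt_float(row.get("pi")),
                    mw_coord=_opt_float(row.get("mw_kda")),
                    iod_raw=_opt_float(row.get("iod_raw")),
                    ppm=_opt_float(row.get("ppm")),
                    protein=(row.get("protein") or "").strip(),
                )
            except (ValueError, KeyError) as exc:
                raise LoadError(f"{path}:{lineno}: malformed row ({exc})") from exc
            per_gel.setdefault(rec.gel_id, []).append(rec)
    tables = {gel: SpotTable(gel_id=gel, records=recs) for gel, recs in per_gel.items()}
    if require_ppm_closure:
        for gel, table in tables.items():
            if not table.ppm_closure_ok():
                raise ValidationError(f"{path}: gel {gel!r} ppm does not sum to 1e6")
    return tables


def read_spot_table(
    path: str | Path,
    gel_id: str | None = None,
    delimiter: str = ",",
) -> SpotTable:
    """Read one gel's spot table; ``gel_id`` selects among stacked gels."""
    tables = read_spot_tables(path, delimiter=delimiter)
    if not tables:
        return SpotTable(gel_id=gel_id or "", records=[])
    if gel_id is None:
        if len(tables) > 1:
            raise LoadError(
                f"{path} holds gels {sorted(tables)}; pass gel_id to select one"
            )
        return next(iter(tables.values()))
    if gel_id not in tables:
        raise LoadError(f"{path}: no gel {gel_id!r} (has {sorted(tables)})")
    return tables[gel_id]


def write_spot_table(tables: SpotTable | list[SpotTable], path: str | Path) -> None:
    if isinstance(tables, SpotTable):
        tables = [tables]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPOT_COLUMNS)
        for table in tables:
            for r in table:
                writer.writerow([
                    r.spot_id,
                    r.gel_id,
                    r.protein,
                    "" if r.pi_coord is None else repr(r.pi_coord),
                    "" if r.mw_coord is None else repr(r.mw_coord),
                    "" if r.iod_raw is None else repr(r.iod_raw),
                    "" if r.ppm is None else repr(r.ppm),
                ])


def parse_accession(header: str) -> str:
    """Accession from a FASTA id: 'sp|P02144|MYG_HUMAN' -> 'P02144'."""
    parts = header.split("|")
    if len(parts) >= 2 and parts[0] in {"sp", "tr", "gi"}:
        if parts[0] == "gi":
            return f"gi|{parts[1]}"
        return parts[1]
    return parts[0]


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read protein sequences; accessions parsed from UniProt-style ids.

    Sequences are uppercased and whitespace-stripped; any non-standard
    residue symbol raises a validation error naming the symbols.
    """
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append(
            ProteinEntry(
                accession=parse_accession(rec.id),
                name=rec.description,
                sequence=str(rec.seq),
            )
        )
    return entries


def write_fasta(entries: list[ProteinEntry], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in entries:
            if e.sequence is None:
                continue
            fh.write(f">{e.accession} {e.name}\n" if e.name else f">{e.accession}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i:i + width] + "\n")


def read_peaklist(path: str | Path, format: str = "plain") -> PeakList:
    """Read a centroided peak list (one m/z per line, or MGF blocks).

    Values are sorted ascending; duplicates are retained.
    """
    path = Path(path)
    if format == "plain":
        mz = []
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                mz.append(float(line.split()[0]))
            except ValueError as exc:
                raise LoadError(f"{path}:{lineno}: non-numeric m/z {line!r}") from exc
        return PeakList(source_id=path.stem, mz_values=mz)
    if format == "mgf":
        from pyteomics import mgf

        mz: list[float] = []
        with mgf.MGF(str(path)) as reader:
            for spectrum in reader:
                mz.extend(float(v) for v in spectrum["m/z array"])
        return PeakList(source_id=path.stem, mz_values=mz)
    raise ValueError(f"unknown peak-list format {format!r}")


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{mz:.5f}\n" for mz in peaks.mz_values), encoding="utf-8"
    )


def write_report(results: dict, path: str | Path) -> None:
    """Write a differential/identification report as JSON.

    Key order is insertion order (stable across runs); the file
    round-trips losslessly through :func:`read_report`.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)


def read_gel_image(path: str | Path, bit_depth: int = 12, **cal_kwargs) -> GelImage:
    """Read a gel image from a 16-bit TIFF/PNG container."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        pixels = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        pixels = iio.imread(str(path))
    img = np.asarray(pixels, dtype=float)
    from .model import AxisCalibration

    cal = AxisCalibration(shape=img.shape, **cal_kwargs) if cal_kwargs else None
    return GelImage(pixels=img, bit_depth=bit_depth, calibration=cal, gel_id=path.stem)


def write_gel_image(image: GelImage, path: str | Path) -> None:
    path = Path(path)
    pixels = np.round(image.pixels).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), pixels)
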