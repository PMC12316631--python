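"""File-format adapters: compound tables (TSV), reference databases (TSV)
and MGF peak lists (via pyteomics).

The sequence-string grammar in all tables is dash-joined tokens, cap first
and amino alcohol (or numeric residual mass) last; a skipped module is the
token ``(skip)`` so it cannot collide with the dash joiner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import ReferenceEntry
from .assembly import Peak, PeakList
from .chemistry import (
    ResidueLibrary,
    SequenceModel,
    UnknownTokenError,
    default_library,
    parse_sequence,
)

__all__ = [
    "CompoundTableRow",
    "read_compound_table",
    "write_compound_table",
    "read_reference_db",
    "read_mgf",
    "write_mgf",
    "packaged_path",
    "load_sf1_table",
    "load_lipopeptaibol_table",
    "load_reference_fixture",
]

_COMPOUND_COLUMNS = [
    "name",
    "strain",
    "sequence",
    "reported_precursor",
    "b",
    "y",
    "rt",
    "pct_peptaibiome",
    "pct_class",
]


@dataclass
class CompoundTableRow:
    """One row of a compound table (one identified compound per strain)."""

    name: str
    strain: str
    seq: SequenceModel
    reported_precursor: float | None = None
    b: float | None = None
    y: float | None = None
    rt: float | None = None
    pct_peptaibiome: float | None = None
    pct_class: float | None = None


def read_compound_table(
    path: str | Path, library: ResidueLibrary | None = None
) -> list[CompoundTableRow]:
    """Read a TSV compound table, validating every sequence string.

    A malformed token raises an error naming the row and the token.
    """
    lib = library or default_library()
    df = pd.read_csv(path, sep="\t")
    rows = []
    for i, rec in df.iterrows():
        try:
            seq = parse_sequence(
                rec["sequence"],
                lib,
                label=str(rec["name"]),
                rt=None if pd.isna(rec.get("rt")) else float(rec["rt"]),
            )
        except UnknownTokenError as exc:
            raise ValueError(
                f"{path}, row {i + 2}: bad token in sequence "
                f"{rec['sequence']!r}: {exc}"
            ) from exc

        def opt(col):
            v = rec.get(col)
            return None if v is None or pd.isna(v) else float(v)

        rows.append(
            CompoundTableRow(
                name=str(rec["name"]),
                strain=str(rec.get("strain", "")),
                seq=seq,
                reported_precursor=opt("reported_precursor"),
                b=opt("b"),
                y=opt("y"),
                rt=opt("rt"),
                pct_peptaibiome=opt("pct_peptaibiome"),
                pct_class=opt("pct_class"),
            )
        )
    return rows


def write_compound_table(rows: list[CompoundTableRow], path: str | Path) -> None:
    """Write rows as TSV; numbers at full precision so read/write round-trips."""
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "strain": r.strain,
                "sequence": r.seq.token_string(),
                "reported_precursor": r.reported_precursor,
                "b": r.b,
                "y": r.y,
                "rt": r.rt,
                "pct_peptaibiome": r.pct_peptaibiome,
                "pct_class": r.pct_class,
            }
            for r in rows
        ],
        columns=_COMPOUND_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_reference_db(
    path: str | Path, library: ResidueLibrary | None = None
) -> list[ReferenceEntry]:
    """Read a reference peptaibiotics database TSV (name/sequence/organism/citation)."""
    lib = library or default_library()
    df = pd.read_csv(path, sep="\t")
    out = []
    for i, rec in df.iterrows():
        try:
            seq = parse_sequence(rec["sequence"], lib, label=str(rec["name"]))
        except UnknownTokenError as exc:
            raise ValueError(
                f"{path}, row {i + 2}: bad token in reference sequence: {exc}"
            ) from exc
        out.append(
            ReferenceEntry(
                name=str(rec["name"]),
                sequence=seq,
                organism=str(rec.get("organism", "")),
                citation=str(rec.get("citation", "")),
            )
        )
    return out


def read_mgf(path: str | Path) -> list[PeakList]:
    """Read an MGF file into PeakLists.

    Requires PEPMASS per spectrum block; empty blocks become empty
    PeakLists.  CR/LF line endings are handled by the reader.
    """
    out = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            if "pepmass" not in params:
                raise ValueError(f"{path}: spectrum without PEPMASS")
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = 1
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = params.get("rtinseconds")
            out.append(
                PeakList(
                    peaks=[
                        Peak(float(mz), float(it))
                        for mz, it in zip(spec["m/z array"], spec["intensity array"])
                    ],
                    precursor_mz=precursor,
                    precursor_charge=charge,
                    title=str(params.get("title", "")),
                    rt=float(rt) / 60.0 if rt is not None else None,
                )
            )
    return out


def write_mgf(spectra: list[PeakList], path: str | Path) -> None:
    """Write PeakLists as MGF (one BEGIN IONS block per spectrum, 6 dp)."""
    entries = []
    for s in spectra:
        params = {
            "title": s.title,
            "pepmass": round(s.precursor_mz, 6),
            "charge": f"{s.precursor_charge}+",
        }
        if s.rt is not None:
            params["rtinseconds"] = round(s.rt * 60.0, 3)
        entries.append(
            {
                "params": params,
                "m/z array": [round(p.mz, 6) for p in s.peaks],
                "intensity array": [round(p.intensity, 6) for p in s.peaks],
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def packaged_path(name: str) -> Path:
    """Path of a packaged data file."""
    import importlib.resources

    return Path(str(importlib.resources.files("peptaibiomics.data") / name))


def load_sf1_table(curated_only: bool = False) -> pd.DataFrame:
    """The packaged SF1-peptaibol compound table.

    ``curated_only`` keeps the rows whose printed masses are internally
    consistent and reproduce from their sequences at +-0.02 Da.
    """
    df = pd.read_csv(packaged_path("sf1_peptaibols.tsv"), sep="\t")
    if curated_only:
        df = df[df["consistent"] == "yes"].reset_index(drop=True)
    return df


def load_lipopeptaibol_table(curated_only: bool = False) -> pd.DataFrame:
    """The packaged lipopeptaibol compound table."""
    df = pd.read_csv(packaged_path("lipopeptaibols.tsv"), sep="\t")
    if curated_only:
        df = df[df["consistent"] == "yes"].reset_index(drop=True)
    return df


def load_reference_fixture(library: ResidueLibrary | None = None) -> list[ReferenceEntry]:
    """The packaged curated reference database."""
    return read_reference_db(packaged_path("reference_db.tsv"), library)
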