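"""Relative quantification and peptaibiome composition analytics.

Peptaibols are quantified by the extracted-ion-chromatogram peak area
under their major y ion (the in-source Aib-Pro cleavage product);
lipopeptaibols by the area under [M+H]+.  Areas are inputs here — peak
integration happens upstream on the instrument software.  Summing areas
per strain gives the total production, from which each compound's share of
its class and of the whole peptaibiome follows.  Lipopeptaibols are
further binned by residue count into short (6-7), medium (10-11) and long
(15) classes.

Microheterogeneity analytics: a per-position consensus over co-produced
equal-length variants (the most abundant residue at each position), and
its comparison with the single most-produced sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .chemistry import GAP, SequenceModel

__all__ = [
    "AbundanceRecord",
    "PeptaibiomeSummary",
    "classify",
    "percentages",
    "consensus",
    "consensus_vs_top",
]

FATTY_ACYL_CAPS = {"Oc"}

LENGTH_CLASSES = {
    6: "short",
    7: "short",
    10: "medium",
    11: "medium",
    15: "long",
}


@dataclass(frozen=True)
class AbundanceRecord:
    """EIC peak area of one compound in one strain."""

    compound: str
    strain: str
    compound_class: str  # 'peptaibol' | 'lipopeptaibol'
    residue_count: int
    area: float
    quant_ion: str = ""  # 'y' for peptaibols, 'M+H' for lipopeptaibols
    length_class: str = ""

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")


def classify(seq: SequenceModel) -> tuple[str, str | None]:
    """(class, length_class) of a resolved compound.

    A compound is a lipopeptaibol iff its N-terminal cap is a fatty acyl
    (octanoyl here); peptaibols (acetyl caps) get no length class.
    Lipopeptaibol lengths outside the 6-7/10-11/15 bins are labelled
    'other' with a warning.
    """
    if seq.cap in FATTY_ACYL_CAPS:
        n = seq.length()
        cls = LENGTH_CLASSES.get(n)
        if cls is None:
            warnings.warn(
                f"lipopeptaibol of {n} residues outside the short/medium/long "
                "bins; labelled 'other'",
                stacklevel=2,
            )
            cls = "other"
        return "lipopeptaibol", cls
    return "peptaibol", None


def record_for(
    seq: SequenceModel, strain: str, area: float, name: str | None = None
) -> AbundanceRecord:
    """Build an AbundanceRecord with the class-appropriate quant ion."""
    cls, length_class = classify(seq)
    return AbundanceRecord(
        compound=name or seq.label or seq.token_string(),
        strain=strain,
        compound_class=cls,
        residue_count=seq.length(),
        area=area,
        quant_ion="M+H" if cls == "lipopeptaibol" else "y",
        length_class=length_class or "",
    )


@dataclass
class PeptaibiomeSummary:
    """Per-strain class shares and per-compound percentage structure."""

    per_compound: pd.DataFrame  # compound, strain, class, pct_class, pct_peptaibiome
    per_strain: pd.DataFrame  # strain x {peptaibol, short/medium/long lipopeptaibol} shares


def _strain_group(rec: AbundanceRecord) -> str:
    if rec.compound_class == "peptaibol":
        return "peptaibol"
    return f"{rec.length_class or 'other'} lipopeptaibol"


def percentages(records: list[AbundanceRecord]) -> PeptaibiomeSummary:
    """Relative quantification of a peptaibiome from EIC areas.

    Per compound: share of its class total within the strain and share of
    the strain's whole peptaibiome.  Per strain: class shares (peptaibol
    and short/medium/long lipopeptaibol), which sum to 100 before
    rounding.  All percentages are on the 0-100 scale at full precision;
    round only for display.
    """
    if not records:
        raise ValueError("no abundance records")
    df = pd.DataFrame(
        {
            "compound": [r.compound for r in records],
            "strain": [r.strain for r in records],
            "compound_class": [r.compound_class for r in records],
            "group": [_strain_group(r) for r in records],
            "residue_count": [r.residue_count for r in records],
            "area": [r.area for r in records],
        }
    )
    totals = df.groupby("strain")["area"].transform("sum")
    if (df.groupby("strain")["area"].sum() == 0).any():
        raise ValueError("all-zero areas for a strain: percentages undefined")
    class_totals = df.groupby(["strain", "compound_class"])["area"].transform("sum")
    df["pct_peptaibiome"] = df["area"] / totals * 100.0
    df["pct_class"] = df["area"] / class_totals * 100.0
    per_strain = (
        df.groupby(["strain", "group"])["area"].sum().unstack(fill_value=0.0)
    )
    per_strain = per_strain.div(per_strain.sum(axis=1), axis=0) * 100.0
    return PeptaibiomeSummary(per_compound=df, per_strain=per_strain)


def _position_matrix(seqs: list[SequenceModel]) -> list[tuple[str, ...]]:
    rows = [s.positions() for s in seqs]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(
            f"consensus needs equal-length sequences (after gap "
            f"reconciliation); got lengths {sorted(lengths)}"
        )
    return rows


def consensus(
    seqs: list[SequenceModel],
    weights: list[float] | None = None,
    mode: str = "unweighted",
) -> tuple[SequenceModel, pd.DataFrame]:
    """Per-position consensus over equal-length sequence variants.

    ``mode='unweighted'`` (default) counts each sequence once — the most
    abundant residue *present* at each position; ``mode='weighted'``
    weights each sequence by its compound abundance.  Gap markers count as
    a token, so skip variants keep full-length positions aligned.  Ties are
    broken alphabetically and flagged in the variant table.

    Returns the consensus sequence and a tidy variant table with columns
    position/token/weight/share/tie.
    """
    if not seqs:
        raise ValueError("no sequences for consensus")
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"mode must be 'weighted' or 'unweighted', got {mode!r}")
    if weights is None:
        weights = [1.0] * len(seqs)
    if len(weights) != len(seqs):
        raise ValueError("weights and sequences differ in length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if mode == "unweighted":
        weights = [1.0] * len(seqs)
    rows = _position_matrix(seqs)
    n_pos = len(rows[0])
    cons_tokens: list[str] = []
    records = []
    for p in range(n_pos):
        tally: dict[str, float] = {}
        for row, w in zip(rows, weights):
            tally[row[p]] = tally.get(row[p], 0.0) + w
        total = sum(tally.values())
        top = max(tally.values())
        winners = sorted(t for t, w in tally.items() if w == top)
        tie = len(winners) > 1
        cons_tokens.append(winners[0])
        for tok, w in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])):
            records.append(
                {
                    "position": p + 1,
                    "token": tok,
                    "weight": w,
                    "share": w / total * 100.0 if total else float("nan"),
                    "tie": tie and w == top,
                }
            )
    template = seqs[0]
    cons = SequenceModel(
        cap=template.cap,
        residues=tuple(cons_tokens[:-1]),
        terminus=cons_tokens[-1],
        label="consensus",
    )
    return cons, pd.DataFrame(records)


def consensus_vs_top(
    seqs: list[SequenceModel],
    weights: list[float],
    mode: str = "unweighted",
) -> list[tuple[int, str, str]]:
    """Positions where the consensus differs from the most-produced variant.

    Returns (position, consensus token, top token) tuples; empty when the
    most abundant sequence is also the per-position consensus.
    """
    if len(weights) != len(seqs):
        raise ValueError("weights and sequences differ in length")
    cons, _ = consensus(seqs, weights, mode=mode)
    top_seq = max(zip(seqs, weights), key=lambda sw: sw[1])[0]
    cpos = cons.positions()
    tpos = top_seq.positions()
    return [
        (i, c, t)
        for i, (c, t) in enumerate(zip(cpos, tpos), start=1)
        if c != t
    ]
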