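"""Theoretical b/y fragment-ion prediction for peptaibols and lipopeptaibols.

Long peptaibols cleave between the central Aib and Pro residues already in
the ion source, yielding one diagnostic N-terminal b ion (acylium) and one
C-terminal y ion (protonated amine).  MS2 of either in-source fragment, or
of the whole [M+H]+ for lipopeptaibols, produces b/y ladders whose
consecutive mass differences are the residue masses — the basis of de novo
sequencing.  Only singly charged ions are modeled, with optional water
loss; a-ions and internal ions are not generated.

Ion arithmetic (all masses monoisotopic, Da):

    b_k = cap_delta + sum(first k residues) + proton
    y_j = sum(last j-1 residues) + alcohol_free + proton

so for every bond ``b_k + y_(N-k) = [M+H]+ + proton``.  The sum b + y is
exposed as :func:`reported_precursor`: it is the convention used for the
precursor column of peptaibol compound tables in this field, one proton
above the true protonated mass (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .chemistry import (
    GAP,
    PROTON,
    WATER,
    ResidueLibrary,
    SequenceModel,
    default_library,
)

__all__ = [
    "FragmentIon",
    "NoDiagnosticSiteError",
    "AmbiguousCleavageError",
    "diagnostic_pair",
    "reported_precursor",
    "ladder",
    "water_loss",
]


class NoDiagnosticSiteError(ValueError):
    """Sequence has no Pro, hence no diagnostic in-source cleavage site."""


class AmbiguousCleavageError(ValueError):
    """More than one Pro: the diagnostic site is ambiguous."""

    def __init__(self, sites: list[int]):
        super().__init__(
            f"multiple Pro residues; candidate cleavage bonds before "
            f"positions {sites}"
        )
        self.sites = sites


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical fragment ion.

    ``index`` counts residues in the fragment (for y ions the amino alcohol
    counts as one).  ``cleavage_site`` is the 1-based index of the broken
    bond, counting bonds between consecutive residue units from the
    N-terminus.  Charge is always +1.
    """

    series: str  # 'b' | 'y'
    index: int
    mz: float
    cleavage_site: int
    loss: str = "none"  # 'none' | 'H2O'
    charge: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"series must be 'b' or 'y', got {self.series!r}")
        if self.loss not in ("none", "H2O"):
            raise ValueError(f"unsupported neutral loss {self.loss!r}")


def _unit_masses(seq: SequenceModel, lib: ResidueLibrary) -> list[float]:
    """Masses of the residue units in order: non-gap internals + terminus."""
    masses = [lib.residue_mass(t) for t in seq.internal_tokens()]
    masses.append(lib.residue_mass(seq.terminus))
    return masses


def ladder(
    seq: SequenceModel,
    series: str,
    bonds: Iterable[int] | None = None,
    library: ResidueLibrary | None = None,
) -> list[FragmentIon]:
    """Full (or bond-restricted) b- or y-ion ladder of a resolved sequence.

    A sequence of N residue units (non-gap internal residues plus the amino
    alcohol) has N-1 bonds, numbered 1..N-1 from the N-terminus.  ``bonds``
    restricts the ladder to a sub-fragment scope; an empty scope yields an
    empty list.  Ions are returned in strictly increasing m/z.
    """
    lib = library or default_library()
    masses = _unit_masses(seq, lib)
    n = len(masses)
    scope = range(1, n) if bonds is None else sorted(set(bonds))
    for k in scope:
        if not 1 <= k <= n - 1:
            raise ValueError(f"bond {k} outside 1..{n - 1}")
    cap = lib.residue_mass(seq.cap)
    ions = []
    if series == "b":
        prefix = cap + PROTON
        csum = 0.0
        sums = []
        for m in masses[:-1]:
            csum += m
            sums.append(csum)
        for k in scope:
            ions.append(
                FragmentIon(series="b", index=k, mz=prefix + sums[k - 1], cleavage_site=k)
            )
    elif series == "y":
        csum = 0.0
        suffix = [0.0] * n
        for i in range(n - 1, -1, -1):
            csum += masses[i]
            suffix[i] = csum
        for k in scope:
            j = n - k  # residue units C-terminal of bond k
            ions.append(
                FragmentIon(series="y", index=j, mz=suffix[k] + PROTON, cleavage_site=k)
            )
        ions.sort(key=lambda ion: ion.mz)
    else:
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    return ions


def diagnostic_pair(
    seq: SequenceModel, library: ResidueLibrary | None = None
) -> tuple[FragmentIon, FragmentIon]:
    """The in-source Aib-Pro cleavage pair (b before Pro, y from Pro on).

    Requires exactly one Pro among the internal residues; lipopeptaibols
    without Pro raise :class:`NoDiagnosticSiteError` and are sequenced from
    whole-molecule MS2 instead.
    """
    lib = library or default_library()
    internals = seq.internal_tokens()
    pro_sites = [i + 1 for i, t in enumerate(internals) if t == "Pro"]
    if not pro_sites:
        raise NoDiagnosticSiteError(
            f"{seq.label or seq.token_string()}: no Pro residue, no in-source "
            "diagnostic cleavage"
        )
    if len(pro_sites) > 1:
        raise AmbiguousCleavageError(pro_sites)
    bond = pro_sites[0] - 1  # bond N-terminal of Pro
    (b_ion,) = ladder(seq, "b", bonds=[bond], library=lib)
    (y_ion,) = ladder(seq, "y", bonds=[bond], library=lib)
    return b_ion, y_ion


def reported_precursor(seq: SequenceModel, library: ResidueLibrary | None = None) -> float:
    """Sum of the diagnostic b and y ion m/z values.

    This is the precursor convention of peptaibol compound tables (printed
    as the "[M+H]+" column): numerically one proton above the true
    protonated molecular ion, because both fragments carry a proton.
    """
    b_ion, y_ion = diagnostic_pair(seq, library)
    return b_ion.mz + y_ion.mz


def water_loss(ion: FragmentIon) -> FragmentIon:
    """The corresponding [ion - H2O]+ fragment."""
    if ion.loss != "none":
        raise ValueError(f"ion already carries a neutral loss ({ion.loss})")
    return replace(ion, mz=ion.mz - WATER, loss="H2O")
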