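"""Residue library and monoisotopic mass calculus for peptaibol-type molecules.

Peptaibols are linear fungal peptides rich in nonproteinogenic residues
(Aib, Iva), N-terminally acylated (acetyl for peptaibols, a fatty acyl such
as octanoyl for lipopeptaibols) and terminated by a C-terminal amino
alcohol.  The mass bookkeeping used throughout this package is:

    M(neutral) = cap_delta + sum(residue masses) + alcohol_free_mass

where *cap_delta* is the neutral substitution delta of the acyl cap
(replacing one amine hydrogen), residue masses are amino-acid monoisotopic
masses minus water, and the amino alcohol enters with its free-molecule
mass.  The two terminal hydrogens of the usual peptide formula cancel
against the cap/alcohol conventions, so no +H2O term appears.

Isobaric residues that MS cannot distinguish are exposed under ambiguity
codes: ``Lxx`` (Leu/Ile) and ``Vxx`` (Val/Iva), plus the corresponding
amino alcohols ``Lxxol``/``Vxxol``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PROTON",
    "HYDROGEN",
    "WATER",
    "SODIUM_CATION",
    "GAP",
    "ADDUCTS",
    "ResidueDef",
    "ResidueLibrary",
    "SequenceModel",
    "UnknownTokenError",
    "UnresolvedSequenceError",
    "default_library",
    "parse_sequence",
    "neutral_mass",
    "mh_plus",
    "adduct_mz",
]

# Physical constants (monoisotopic, Da).  SODIUM_CATION is atomic Na minus
# one electron mass.
PROTON = 1.007276
HYDROGEN = 1.007825
WATER = 18.010565
SODIUM_CATION = 22.989218

#: Gap marker for a skipped biosynthetic module.  Contributes zero mass and
#: keeps its 1-based position in the template coordinate system.
GAP = "(skip)"

#: Supported precursor adducts: name -> (total cation mass, charge).
ADDUCTS = {
    "M+H": (PROTON, 1),
    "M+Na": (SODIUM_CATION, 1),
    "M+2H": (2 * PROTON, 2),
    "M+2Na": (2 * SODIUM_CATION, 2),
    "M+H+Na": (PROTON + SODIUM_CATION, 2),
}


class UnknownTokenError(KeyError):
    """Raised when a residue token is not registered in the library."""

    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown residue token {self.token!r}; not in the residue library"


class UnresolvedSequenceError(ValueError):
    """Raised when an operation needs a resolved C-terminus but the sequence
    carries only an unexplained residual mass."""


@dataclass(frozen=True)
class ResidueDef:
    """One chemical building block.

    ``mono_mass`` semantics depend on ``residue_class``:

    - ``internal``: residue mass (amino acid minus water),
    - ``amino_alcohol``: free-molecule mass,
    - ``acyl_cap``: neutral substitution delta replacing one amine hydrogen.
    """

    token: str
    residue_class: str  # internal | amino_alcohol | acyl_cap
    mono_mass: float
    formula: str = ""
    ambiguity: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.residue_class not in ("internal", "amino_alcohol", "acyl_cap"):
            raise ValueError(f"bad residue class {self.residue_class!r}")
        if not self.mono_mass > 0:
            raise ValueError(f"mono_mass must be positive for {self.token!r}")


class ResidueLibrary:
    """Token-keyed registry of residues, amino alcohols and acyl caps.

    The packaged default is loaded from ``data/residues.tsv``; users can
    append or override tokens via :meth:`register` or an extra TSV/config
    without code changes.
    """

    def __init__(self, residues: Iterable[ResidueDef] = ()):
        self._by_token: dict[str, ResidueDef] = {}
        for r in residues:
            self.register(r)

    def register(self, residue: ResidueDef) -> None:
        self._by_token[residue.token] = residue

    def __contains__(self, token: str) -> bool:
        return token in self._by_token

    def __iter__(self):
        return iter(self._by_token.values())

    def __len__(self) -> int:
        return len(self._by_token)

    def get(self, token: str) -> ResidueDef:
        try:
            return self._by_token[token]
        except KeyError:
            raise UnknownTokenError(token) from None

    def residue_mass(self, token: str) -> float:
        """Monoisotopic mass of one token (class-dependent semantics)."""
        return self.get(token).mono_mass

    def tokens(self, residue_class: str | None = None) -> list[str]:
        return [
            r.token
            for r in self._by_token.values()
            if residue_class is None or r.residue_class == residue_class
        ]

    def canonical(self, token: str) -> str:
        """Collapse concrete isomers onto their ambiguity code (Leu -> Lxx)."""
        rd = self.get(token)
        for other in self._by_token.values():
            if token in other.ambiguity:
                return other.token
        return rd.token

    def equivalent(self, a: str, b: str) -> bool:
        """True if two tokens are the same residue up to isobaric ambiguity.

        ``Lxx`` matches ``Leu`` and ``Ile``; every token matches itself.
        Gap markers match only gap markers.
        """
        if a == b:
            return True
        if a == GAP or b == GAP:
            return False
        return self.canonical(a) == self.canonical(b)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueLibrary":
        lib = cls()
        lib.load_tsv(path)
        return lib

    def load_tsv(self, path: str | Path) -> None:
        """Append rows from a TSV with columns token/class/formula/mono_mass/ambiguity."""
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                amb = ""
                if "ambiguity" in idx and len(parts) > idx["ambiguity"]:
                    amb = parts[idx["ambiguity"]]
                self.register(
                    ResidueDef(
                        token=parts[idx["token"]],
                        residue_class=parts[idx["class"]],
                        formula=parts[idx["formula"]] if "formula" in idx else "",
                        mono_mass=float(parts[idx["mono_mass"]]),
                        ambiguity=frozenset(t for t in amb.split(",") if t),
                    )
                )


_DEFAULT: ResidueLibrary | None = None


def default_library() -> ResidueLibrary:
    """The packaged residue library (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        path = importlib.resources.files("peptaibiomics.data") / "residues.tsv"
        _DEFAULT = ResidueLibrary.from_tsv(str(path))
    return _DEFAULT


def residue_mass(token: str, library: ResidueLibrary | None = None) -> float:
    """Monoisotopic mass of a registered token."""
    return (library or default_library()).residue_mass(token)


@dataclass(frozen=True)
class SequenceModel:
    """One compound: acyl cap, ordered internal residues, C-terminus.

    ``residues`` may contain :data:`GAP` markers for skipped biosynthetic
    modules; gaps hold a 1-based position but contribute no mass.  Exactly
    one of ``terminus`` (amino-alcohol token) and ``residual_mass`` (an
    unresolved C-terminal mass in Da) is set.
    """

    cap: str
    residues: tuple[str, ...]
    terminus: str | None = None
    residual_mass: float | None = None
    label: str = ""
    rt: float | None = None

    def __post_init__(self) -> None:
        if (self.terminus is None) == (self.residual_mass is None):
            raise ValueError(
                "exactly one of terminus and residual_mass must be given"
            )
        object.__setattr__(self, "residues", tuple(self.residues))

    @property
    def resolved(self) -> bool:
        return self.terminus is not None

    def internal_tokens(self) -> tuple[str, ...]:
        """Internal residues with gap markers removed."""
        return tuple(t for t in self.residues if t != GAP)

    def length(self) -> int:
        """Residue count: non-gap internal residues plus the terminus."""
        return len(self.internal_tokens()) + (1 if self.resolved else 0)

    def positions(self) -> tuple[str, ...]:
        """Position-indexed token string (gaps included, terminus last)."""
        tail = (self.terminus,) if self.resolved else ()
        return self.residues + tail

    def token_string(self) -> str:
        """Display string: cap-res1-...-terminus, gaps printed as (skip)."""
        tail = self.terminus if self.resolved else f"{self.residual_mass:.0f}"
        return "-".join((self.cap, *self.residues, str(tail)))

    def without_gaps(self) -> "SequenceModel":
        """The same compound with gap markers dropped (raw short sequence)."""
        return replace(self, residues=self.internal_tokens())

    def with_gaps_at(self, positions: Sequence[int]) -> "SequenceModel":
        """Insert gap markers at the given 1-based template positions."""
        out = list(self.residues)
        for p in sorted(positions):
            out.insert(p - 1, GAP)
        return replace(self, residues=tuple(out))


def parse_sequence(
    text: str,
    library: ResidueLibrary | None = None,
    label: str = "",
    rt: float | None = None,
) -> SequenceModel:
    """Parse a dash-joined token string into a :class:`SequenceModel`.

    Grammar: cap first, then internal residues, then either an amino-alcohol
    token or a numeric residual mass; ``(skip)`` marks a skipped module.

    >>> parse_sequence("Ac-Aib-Pro-Lxxol").token_string()
    'Ac-Aib-Pro-Lxxol'
    """
    lib = library or default_library()
    tokens = [t for t in text.split("-") if t != ""]
    if len(tokens) < 2:
        raise ValueError(f"sequence string too short: {text!r}")
    cap = tokens[0]
    if cap not in lib or lib.get(cap).residue_class != "acyl_cap":
        raise UnknownTokenError(cap)
    tail = tokens[-1]
    terminus: str | None = None
    residual: float | None = None
    try:
        residual = float(tail)
    except ValueError:
        if tail not in lib or lib.get(tail).residue_class != "amino_alcohol":
            raise UnknownTokenError(tail) from None
        terminus = tail
    internal = []
    for t in tokens[1:-1]:
        if t == GAP:
            internal.append(GAP)
            continue
        if t not in lib or lib.get(t).residue_class != "internal":
            raise UnknownTokenError(t)
        internal.append(t)
    return SequenceModel(
        cap=cap,
        residues=tuple(internal),
        terminus=terminus,
        residual_mass=residual,
        label=label,
        rt=rt,
    )


def neutral_mass(seq: SequenceModel, library: ResidueLibrary | None = None) -> float:
    """Neutral monoisotopic mass of a resolved compound.

    ``cap_delta + sum(residues) + alcohol_free``; gap markers are skipped.
    """
    lib = library or default_library()
    if not seq.resolved:
        raise UnresolvedSequenceError(
            f"{seq.label or seq.token_string()}: C-terminus is an unresolved "
            "residual mass; neutral mass undefined"
        )
    total = lib.residue_mass(seq.cap) + lib.residue_mass(seq.terminus)
    for t in seq.internal_tokens():
        total += lib.residue_mass(t)
    return total


def mh_plus(seq: SequenceModel, library: ResidueLibrary | None = None) -> float:
    """m/z of the protonated molecular ion [M+H]+."""
    return neutral_mass(seq, library) + PROTON


def adduct_mz(
    seq: SequenceModel,
    adduct: str,
    z: int | None = None,
    library: ResidueLibrary | None = None,
) -> float:
    """m/z of a precursor adduct ion.

    ``adduct`` is one of M+H, M+Na, M+2H, M+2Na, M+H+Na; if ``z`` is given
    it must agree with the adduct's charge.
    """
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; choose from {sorted(ADDUCTS)}")
    cation_mass, charge = ADDUCTS[adduct]
    if z is not None and z != charge:
        raise ValueError(f"adduct {adduct} is {charge}+; got z={z}")
    return (neutral_mass(seq, library) + cation_mass) / charge
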