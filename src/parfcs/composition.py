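"""Branching ratio and average polymer length from PAR digestion products.

Exhaustive digestion of poly(ADP-ribose) with phosphodiesterase and alkaline
phosphatase yields three nucleosides that report on polymer architecture:
adenosine (Ado) from chain termini, ribosyl-adenosine (R-Ado) from linear
internal units, and di-ribosyl-adenosine (R2-Ado) from branch points.  A
molecule of ``n`` units with ``b`` branch points digests to

    Ado = b + 1,   R2-Ado = b,   R-Ado = n - 2b - 1        (n >= 2b + 1)

so over any ensemble the totals satisfy ``Ado + R-Ado + R2-Ado = units`` and
``Ado - R2-Ado = molecules``, making the two summary statistics exact:

    BR [%] = R2-Ado / (Ado + R-Ado + R2-Ado) * 100   (branch fraction)
    APL    = (Ado + R-Ado + R2-Ado) / (Ado - R2-Ado) (mean chain length)

Both are ratios, hence invariant under uniform rescaling of the amounts
(pmol vs mole fractions give identical results).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class NucleosideCounts:
    """Quantified digestion products (any common unit: pmol, mole fraction...)."""

    ado: float
    r_ado: float
    r2_ado: float

    def __post_init__(self):
        if self.ado < 0 or self.r_ado < 0 or self.r2_ado < 0:
            raise InvalidParameterError("amounts must be >= 0")

    @property
    def total(self) -> float:
        return self.ado + self.r_ado + self.r2_ado

    def __add__(self, other: "NucleosideCounts") -> "NucleosideCounts":
        return NucleosideCounts(
            self.ado + other.ado,
            self.r_ado + other.r_ado,
            self.r2_ado + other.r2_ado,
        )


def branching_ratio(c: NucleosideCounts) -> float:
    """Branch-point fraction among all units, in percent (0 <= BR < 100)."""
    if c.total <= 0:
        raise InvalidParameterError("all-zero nucleoside amounts: BR undefined")
    return 100.0 * c.r2_ado / c.total


def average_polymer_length(c: NucleosideCounts) -> float:
    """Mean ADP-ribose units per molecule.

    Exact for any ensemble following the digestion bookkeeping above; the
    denominator ``Ado - R2-Ado`` counts molecules, so it must be positive.
    """
    denom = c.ado - c.r2_ado
    if denom <= 0:
        raise InvalidParameterError(
            "Ado must exceed R2-Ado (termini outnumber branch points)"
        )
    return c.total / denom


def branch_points_per_molecule(c: NucleosideCounts) -> float:
    """Mean branch points per molecule: R2-Ado / (Ado - R2-Ado).

    ``branching_ratio(c)/100 * average_polymer_length(c)`` is an equivalent
    rearrangement (R2Ado/total * total/molecules); both count exactly
    b_total / n_molecules.
    """
    denom = c.ado - c.r2_ado
    if denom <= 0:
        raise InvalidParameterError(
            "Ado must exceed R2-Ado (termini outnumber branch points)"
        )
    return c.r2_ado / denom
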