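"""Fatty-acid functional-group chemistry and the HCL/DS statistics.

A straight-chain fatty acid ``Cn:d`` (n carbons, d C=C double bonds) is
modelled as CH3-(chain)-COOH: exactly one terminal methyl, one carboxyl,
``2d`` unsaturated CH carbons and ``n - 2 - 2d`` methylene carbons.  Two
scalar descriptors summarise a molecule or a tissue composition:

* **HCL** (hydrocarbon chain length) = (CH3 + CH2 + CH + COOH) / CH3,
  which for a straight chain is exactly the carbon number, and
* **DS** (degree of saturation) = CH2 / (CH + CH2), 1 for saturated
  chains and decreasing with every double bond.

Tissue-level values are computed from a molar fatty-acid composition
(the gas-chromatography stand-in) either by pooling group counts over
all molecules (default) or as molar-fraction-weighted means of the
per-molecule descriptors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FattyAcid",
    "FunctionalGroupCounts",
    "FattyAcidComposition",
    "TissueLipidProfile",
    "DEFAULT_PANEL",
    "parse_fatty_acid",
    "count_functional_groups",
    "fatty_acid_hcl",
    "fatty_acid_ds",
    "composition_profile",
    "hcl_ds_scatter_data",
    "round_half_up",
]

_FRACTION_TOL = 1e-9

_SHORTHAND_RE = re.compile(
    r"""^\s*C?\s*(?P<carbons>\d+)\s*:\s*(?P<dbonds>\d+)
        \s*(?:\(\s*n\s*-\s*\d+\s*\))?\s*$""",
    re.IGNORECASE | re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A straight-chain fatty acid with ``carbons`` C atoms and
    ``double_bonds`` C=C bonds (the ``Cn:d`` shorthand)."""

    carbons: int
    double_bonds: int = 0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise ValueError(
                f"carbons must be >= 4, got {self.carbons} "
                "(shorter chains are out of model)"
            )
        max_d = (self.carbons - 2) // 2
        if not 0 <= self.double_bonds <= max_d:
            raise ValueError(
                f"double_bonds must be in [0, {max_d}] for C{self.carbons}, "
                f"got {self.double_bonds}"
            )

    @property
    def shorthand(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name or self.shorthand


@dataclass(frozen=True)
class FunctionalGroupCounts:
    """CH3/CH2/CH/COOH group counts of one molecule."""

    n_ch3: int
    n_ch2: int
    n_ch: int
    n_cooh: int

    @property
    def total_carbons(self) -> int:
        return self.n_ch3 + self.n_ch2 + self.n_ch + self.n_cooh


def parse_fatty_acid(text: str) -> FattyAcid:
    """Parse shorthand like ``16:0``, ``C18:2`` or ``18:2(n-6)``.

    The ``(n-x)`` double-bond-position suffix is accepted and ignored:
    bond position is invisible to CH/CH2/CH3 counting.
    """
    m = _SHORTHAND_RE.match(text)
    if m is None:
        raise ValueError(f"unrecognized fatty-acid shorthand: {text!r}")
    return FattyAcid(
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("dbonds")),
        name=text.strip(),
    )


def count_functional_groups(fa: FattyAcid) -> FunctionalGroupCounts:
    """Count CH3, CH2, CH and COOH groups of a straight-chain fatty acid.

    One CH3 terminus, one COOH terminus, two CH carbons per double bond,
    and the remaining ``carbons - 2 - 2*double_bonds`` carbons are CH2.
    """
    n_ch = 2 * fa.double_bonds
    n_ch2 = fa.carbons - 2 - n_ch
    if n_ch2 < 0:  # unreachable through FattyAcid invariants; guard anyway
        raise ValueError(f"no straight-chain structure for {fa.shorthand}")
    return FunctionalGroupCounts(n_ch3=1, n_ch2=n_ch2, n_ch=n_ch, n_cooh=1)


def fatty_acid_hcl(fa: FattyAcid) -> float:
    """Hydrocarbon chain length: (CH3 + CH2 + CH + COOH) / CH3.

    Equals the carbon number exactly for any straight chain.
    """
    g = count_functional_groups(fa)
    return (g.n_ch3 + g.n_ch2 + g.n_ch + g.n_cooh) / g.n_ch3


def fatty_acid_ds(fa: FattyAcid) -> float:
    """Degree of saturation: CH2 / (CH + CH2), in [0, 1].

    1 iff the chain is fully saturated; each double bond converts two
    CH2 groups into CH and lowers the ratio.
    """
    g = count_functional_groups(fa)
    denom = g.n_ch + g.n_ch2
    if denom == 0:
        raise ValueError(f"DS undefined for {fa.shorthand}: no CH/CH2 carbons")
    return g.n_ch2 / denom


#: 16 common liver fatty acids (configurable stand-in panel).
DEFAULT_PANEL: tuple[FattyAcid, ...] = tuple(
    parse_fatty_acid(s)
    for s in (
        "14:0", "16:0", "16:1", "17:0", "18:0", "18:1", "18:2", "18:3",
        "20:1", "20:2", "20:3", "20:4", "20:5", "22:4", "22:5", "22:6",
    )
)


@dataclass(frozen=True)
class FattyAcidComposition:
    """Molar fatty-acid composition of one tissue sample.

    ``entries`` maps each fatty acid to its molar fraction (fractions are
    non-negative and sum to 1); ``total_lipid`` is mg lipid per g tissue
    when known.
    """

    entries: tuple[tuple[FattyAcid, float], ...]
    total_lipid: float | None = None

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("composition must contain at least one fatty acid")
        fas = [fa for fa, _ in self.entries]
        if len(set(fas)) != len(fas):
            raise ValueError("fatty acids in a composition must be unique")
        fracs = np.array([f for _, f in self.entries], dtype=float)
        if np.any(fracs < -_FRACTION_TOL):
            raise ValueError("molar fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"molar fractions must sum to 1, got {fracs.sum():.9f}"
            )

    @classmethod
    def from_dict(
        cls,
        fractions: dict[str | FattyAcid, float],
        total_lipid: float | None = None,
    ) -> "FattyAcidComposition":
        entries = tuple(
            (fa if isinstance(fa, FattyAcid) else parse_fatty_acid(fa), float(f))
            for fa, f in fractions.items()
        )
        return cls(entries=entries, total_lipid=total_lipid)

    @property
    def fatty_acids(self) -> tuple[FattyAcid, ...]:
        return tuple(fa for fa, _ in self.entries)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.entries], dtype=float)


@dataclass(frozen=True)
class TissueLipidProfile:
    """Tissue-level HCL, DS and (optionally) total lipid of one sample."""

    hcl: float
    ds: float
    total_lipid: float | None = None
    label: str = ""


def composition_profile(
    comp: FattyAcidComposition,
    mode: Literal["pooled", "weighted"] = "pooled",
) -> TissueLipidProfile:
    """Tissue-level HCL and DS of a molar composition.

    ``pooled`` (default) forms the HCL and DS ratios from molar-fraction
    pooled group counts over all molecules — the ratio computed "for each
    sample".  ``weighted`` instead averages the per-molecule HCL and DS
    with molar-fraction weights (the vector-combination reading of the
    HCL/DS plot).  The two agree for HCL (every straight chain has one
    CH3) but differ slightly for DS.
    """
    groups = [count_functional_groups(fa) for fa in comp.fatty_acids]
    f = comp.fractions
    if mode == "pooled":
        ch3 = float(f @ [g.n_ch3 for g in groups])
        ch2 = float(f @ [g.n_ch2 for g in groups])
        ch = float(f @ [g.n_ch for g in groups])
        cooh = float(f @ [g.n_cooh for g in groups])
        hcl = (ch3 + ch2 + ch + cooh) / ch3
        ds = ch2 / (ch + ch2)
    elif mode == "weighted":
        hcl = float(f @ [fatty_acid_hcl(fa) for fa in comp.fatty_acids])
        ds = float(f @ [fatty_acid_ds(fa) for fa in comp.fatty_acids])
    else:
        raise ValueError(f"mode must be 'pooled' or 'weighted', got {mode!r}")
    return TissueLipidProfile(hcl=hcl, ds=ds, total_lipid=comp.total_lipid)


def hcl_ds_scatter_data(
    profiles: Sequence[TissueLipidProfile],
    panel: Iterable[FattyAcid] = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Plot-ready (HCL, DS) table: tissue points plus panel vertices.

    Tissue profiles plot at (hcl, ds); each panel fatty acid contributes a
    vertex at its own (HCL, DS).  Pooled tissue points lie inside the
    convex hull of the panel vertices, so the vertices frame the plot.
    """
    panel = tuple(panel)
    if not profiles or not panel:
        raise ValueError("profiles and panel must be non-empty")
    rows = [
        {"kind": "tissue", "label": p.label, "hcl": p.hcl, "ds": p.ds}
        for p in profiles
    ]
    rows += [
        {
            "kind": "fatty_acid",
            "label": fa.shorthand,
            "hcl": fatty_acid_hcl(fa),
            "ds": fatty_acid_ds(fa),
        }
        for fa in panel
    ]
    return pd.DataFrame(rows, columns=["kind", "label", "hcl", "ds"])


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.625 -> 0.63), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def read_composition_csv(path) -> FattyAcidComposition:
    """Read a composition CSV with columns ``fatty_acid``, ``molar_fraction``
    and optionally ``total_lipid_mg_per_g`` (constant over rows)."""
    df = pd.read_csv(path)
    missing = {"fatty_acid", "molar_fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"composition CSV missing columns: {sorted(missing)}")
    lipid = None
    if "total_lipid_mg_per_g" in df.columns:
        lipid = float(df["total_lipid_mg_per_g"].iloc[0])
    entries = tuple(
        (parse_fatty_acid(str(r.fatty_acid)), float(r.molar_fraction))
        for r in df.itertuples()
    )
    return FattyAcidComposition(entries=entries, total_lipid=lipid)


def write_composition_csv(comp: FattyAcidComposition, path) -> None:
    df = pd.DataFrame(
        {
            "fatty_acid": [fa.shorthand for fa in comp.fatty_acids],
            "molar_fraction": comp.fractions,
        }
    )
    if comp.total_lipid is not None:
        df["total_lipid_mg_per_g"] = comp.total_lipid
    df.to_csv(path, index=False)
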