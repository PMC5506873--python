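"""Efficiency-corrected relative expression ratios from qPCR Ct tables.

The ratio of a target gene between the two conditions (N-minus over
N-plus), normalized to one or more control genes, is

    R = (1 + E_t)^dCt_t / G,   dCt_g = mean Ct(N+) - mean Ct(N-)

where G is the geometric mean over controls of (1 + E_c)^dCt_c and E is
the fractional primer efficiency in (0, 1]. With all efficiencies equal to
1 this reduces to the familiar 2^-ddCt. Replicates are summarized by the
arithmetic mean Ct; their s.d. is propagated (in log space, one s.d.) to a
ratio interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "CONDITIONS",
    "CtTable",
    "FoldChange",
    "relative_ratio",
    "read_ct_table",
    "read_efficiencies",
]

CONDITIONS = ("Nplus", "Nminus")


@dataclass
class CtTable:
    """Replicate Ct values per (gene, condition), with primer efficiencies."""

    data: pd.DataFrame  # columns: gene, condition, replicate, ct
    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        bad_cond = set(self.data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(
                f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}"
            )
        if (self.data["ct"] <= 0).any():
            raise ValueError("all Ct values must be positive")
        for gene, eff in self.efficiencies.items():
            if not 0 < eff <= 1:
                raise ValueError(
                    f"efficiency for {gene!r} is {eff}; must be in (0, 1]"
                )

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def efficiency(self, gene: str) -> float:
        if gene not in self.efficiencies:
            raise KeyError(f"no primer efficiency for gene {gene!r}")
        return self.efficiencies[gene]

    def delta_ct(self, gene: str) -> tuple[float, float]:
        """(mean Ct(N+) - mean Ct(N-), s.d. of that difference)."""
        sub = self.data[self.data["gene"] == gene]
        stats = {}
        for cond in CONDITIONS:
            cts = sub.loc[sub["condition"] == cond, "ct"]
            if cts.empty:
                raise ValueError(f"gene {gene!r} has no Ct values for {cond}")
            var = float(cts.std(ddof=1) ** 2) if len(cts) > 1 else 0.0
            stats[cond] = (float(cts.mean()), var / len(cts))
        delta = stats["Nplus"][0] - stats["Nminus"][0]
        sd = math.sqrt(stats["Nplus"][1] + stats["Nminus"][1])
        return delta, sd


@dataclass(frozen=True)
class FoldChange:
    gene: str
    ratio: float  # N-minus relative to N-plus
    direction: str  # "increase" | "decrease"
    fold: float  # max(ratio, 1/ratio)
    ratio_low: float
    ratio_high: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


def relative_ratio(
    table: CtTable,
    target: str,
    controls: str | Sequence[str],
    simple_ddct: bool = False,
) -> FoldChange:
    """Relative N-/N+ expression of `target`, normalized to `controls`.

    ``simple_ddct`` ignores the measured efficiencies and uses base 2
    throughout (the classic ddCt shortcut).
    """
    if isinstance(controls, str):
        controls = [controls]
    if not controls:
        raise ValueError("need at least one control gene")

    def base(gene: str) -> float:
        return 2.0 if simple_ddct else 1.0 + table.efficiency(gene)

    d_t, sd_t = table.delta_ct(target)
    b_t = base(target)
    log_r = d_t * math.log(b_t)
    var_log = (sd_t * math.log(b_t)) ** 2
    k = len(controls)
    for ctrl in controls:
        d_c, sd_c = table.delta_ct(ctrl)
        b_c = base(ctrl)
        log_r -= d_c * math.log(b_c) / k
        var_log += (sd_c * math.log(b_c) / k) ** 2
    ratio = math.exp(log_r)
    sd_log = math.sqrt(var_log)
    direction = "increase" if ratio >= 1 else "decrease"
    return FoldChange(
        gene=target,
        ratio=ratio,
        direction=direction,
        fold=max(ratio, 1.0 / ratio),
        ratio_low=math.exp(log_r - sd_log),
        ratio_high=math.exp(log_r + sd_log),
    )


def read_ct_table(ct_path: str | Path, eff_path: str | Path) -> CtTable:
    """Ct TSV (gene, condition, replicate, ct) + efficiency TSV (gene, efficiency)."""
    data = pd.read_csv(ct_path, sep="\t")
    eff = pd.read_csv(eff_path, sep="\t")
    return CtTable(data, dict(zip(eff["gene"], eff["efficiency"].astype(float))))


def read_efficiencies(path: str | Path) -> dict[str, float]:
    eff = pd.read_csv(path, sep="\t")
    return dict(zip(eff["gene"], eff["efficiency"].astype(float)))
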