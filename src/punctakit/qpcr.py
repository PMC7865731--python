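"""qPCR relative quantification: ddCt, Pfaffl, and a minimum-referenced variant.

Three ways of turning replicate Cq tables into treated/untreated fold
changes, with A = mean Cq of the target gene in the untreated sample,
B = mean Cq of the target in the treated sample, F and G the same for the
housekeeping reference gene:

1. ``2^-ddCt``: fold = 2^((A - B) - (F - G)), assuming perfect doubling.
2. Efficiency-corrected (Pfaffl): fold = E_target^(A - B) / E_ref^(F - G),
   with measured primer efficiencies (defaults 1.85 target, 1.97 reference).
3. Minimum-referenced Pfaffl: each gene's quantities are expressed relative
   to its reaction with the lowest mean Cq; the treated/untreated ratio of
   those relative quantities coincides with method 2 up to a gene-wise
   constant that cancels.

Replicates are aggregated as the arithmetic mean of Cq before any
exponentiation. Multiple housekeeping genes can be combined by averaging
their mean Cq; per-reference results are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

CONDITIONS = ("treated", "untreated")
METHODS = ("ddct", "pfaffl", "pfaffl_min_ref")

DEFAULT_E_TARGET = 1.85
DEFAULT_E_REFERENCE = 1.97


@dataclass
class CqTable:
    """Tidy replicate Cq values plus the designated reference genes."""

    df: pd.DataFrame  # columns: gene, condition, replicate, cq
    reference_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "cq"}
        if not required.issubset(self.df.columns):
            raise ParameterError(f"CqTable needs columns {sorted(required)}")
        if not set(self.df["condition"]).issubset(CONDITIONS):
            raise ParameterError(f"conditions must be among {CONDITIONS}")
        cq = self.df["cq"].to_numpy(dtype=float)
        if not np.all(np.isfinite(cq)) or np.any(cq <= 0):
            raise ParameterError("all Cq values must be finite and > 0")
        for ref in self.reference_genes:
            for cond in CONDITIONS:
                if self._subset(ref, cond).empty:
                    raise ParameterError(
                        f"reference gene {ref} missing condition {cond}"
                    )

    def _subset(self, gene: str, condition: str) -> pd.DataFrame:
        return self.df[(self.df["gene"] == gene) & (self.df["condition"] == condition)]

    def mean_cq(self, gene: str, condition: str) -> float:
        sub = self._subset(gene, condition)
        if sub.empty:
            raise ParameterError(f"no Cq data for gene {gene}, condition {condition}")
        return float(sub["cq"].mean())

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.df["gene"]))

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.reference_genes]

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, reference_genes=()) -> "CqTable":
        return cls(df=pd.read_csv(path), reference_genes=list(reference_genes))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class FoldChange:
    """Treated/untreated expression ratio for one gene."""

    gene: str
    method: str
    fold: float
    inputs_used: tuple[float, float, float, float]  # (A, B, F, G) mean Cq
    relative_quantities: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}")
        if not self.fold > 0:
            raise ParameterError("fold must be > 0")


def _abfg(table: CqTable, gene: str, reference) -> tuple[float, float, float, float]:
    """Mean Cq inputs (A, B, F, G); multi-reference Cq is averaged."""
    refs = [reference] if isinstance(reference, str) else list(reference)
    if not refs:
        raise ParameterError("at least one reference gene required")
    a = table.mean_cq(gene, "untreated")
    b = table.mean_cq(gene, "treated")
    f = float(np.mean([table.mean_cq(r, "untreated") for r in refs]))
    g = float(np.mean([table.mean_cq(r, "treated") for r in refs]))
    return a, b, f, g


def ddct_fold(table: CqTable, gene: str, reference=None) -> FoldChange:
    """Relative expression by 2^-ddCt.

    dCt = mean Cq(gene) - mean Cq(reference) per condition; ddCt is the
    treated minus untreated difference; fold = 2^-ddCt.
    """
    reference = reference if reference is not None else table.reference_genes
    a, b, f, g = _abfg(table, gene, reference)
    fold = 2.0 ** ((a - b) - (f - g))
    return FoldChange(gene=gene, method="ddct", fold=float(fold), inputs_used=(a, b, f, g))


def pfaffl_fold(
    table: CqTable,
    gene: str,
    reference=None,
    e_target: float = DEFAULT_E_TARGET,
    e_reference: float = DEFAULT_E_REFERENCE,
) -> FoldChange:
    """Efficiency-corrected fold: E_target^(A-B) / E_reference^(F-G)."""
    for e in (e_target, e_reference):
        if not 1.0 < e <= 2.0:
            raise ParameterError("primer efficiencies must lie in (1, 2]")
    reference = reference if reference is not None else table.reference_genes
    a, b, f, g = _abfg(table, gene, reference)
    fold = e_target ** (a - b) / e_reference ** (f - g)
    return FoldChange(
        gene=gene, method="pfaffl", fold=float(fold), inputs_used=(a, b, f, g)
    )


def pfaffl_min_ref_fold(
    table: CqTable,
    gene: str,
    reference=None,
    e_target: float = DEFAULT_E_TARGET,
    e_reference: float = DEFAULT_E_REFERENCE,
) -> FoldChange:
    """Pfaffl variant referenced to each gene's lowest-mean-Cq reaction.

    For the target and the reference gene alike, the per-condition quantity
    is expressed relative to that gene's reaction with the lowest mean Cq
    (its most abundant reaction): q(cond) = E^(minCq - meanCq(cond)). The
    reported fold is the treated/untreated ratio of target over reference
    relative quantities, which agrees with the plain efficiency-corrected
    fold because the gene-wise normalization constants cancel.
    """
    for e in (e_target, e_reference):
        if not 1.0 < e <= 2.0:
            raise ParameterError("primer efficiencies must lie in (1, 2]")
    reference = reference if reference is not None else table.reference_genes
    a, b, f, g = _abfg(table, gene, reference)
    t_min = min(a, b)
    r_min = min(f, g)
    q = {
        "target_untreated": e_target ** (t_min - a),
        "target_treated": e_target ** (t_min - b),
        "reference_untreated": e_reference ** (r_min - f),
        "reference_treated": e_reference ** (r_min - g),
    }
    fold = (q["target_treated"] / q["reference_treated"]) / (
        q["target_untreated"] / q["reference_untreated"]
    )
    return FoldChange(
        gene=gene,
        method="pfaffl_min_ref",
        fold=float(fold),
        inputs_used=(a, b, f, g),
        relative_quantities=q,
    )


def relative_quantities_min_ref(
    table: CqTable, gene: str, e: float = DEFAULT_E_TARGET
) -> dict[str, float]:
    """Per-condition quantities of one gene relative to its lowest mean Cq."""
    means = {cond: table.mean_cq(gene, cond) for cond in CONDITIONS
             if not table._subset(gene, cond).empty}
    if len(means) < 1:
        raise ParameterError(f"no reactions for gene {gene}")
    cq_min = min(means.values())
    return {cond: e ** (cq_min - m) for cond, m in means.items()}


def multi_reference_summary(
    table: CqTable,
    gene: str,
    method: str = "ddct",
    e_target: float = DEFAULT_E_TARGET,
    e_reference: float = DEFAULT_E_REFERENCE,
) -> dict[str, FoldChange]:
    """Fold change per reference gene plus a combined value.

    The combined estimate uses the arithmetic mean of the reference genes'
    mean Cq (a documented choice; the combination rule is not standardized).
    """
    if not table.reference_genes:
        raise ParameterError("table declares no reference genes")
    fn = {
        "ddct": lambda ref: ddct_fold(table, gene, ref),
        "pfaffl": lambda ref: pfaffl_fold(table, gene, ref, e_target, e_reference),
        "pfaffl_min_ref": lambda ref: pfaffl_min_ref_fold(
            table, gene, ref, e_target, e_reference
        ),
    }[method]
    out = {ref: fn(ref) for ref in table.reference_genes}
    out["combined"] = fn(table.reference_genes)
    return out


def fold_change_table(table: CqTable, method: str = "ddct", **kwargs) -> pd.DataFrame:
    """Fold changes for every target gene as a tidy DataFrame."""
    fn = {"ddct": ddct_fold, "pfaffl": pfaffl_fold, "pfaffl_min_ref": pfaffl_min_ref_fold}[
        method
    ]
    rows = []
    for gene in table.target_genes:
        fc = fn(table, gene, **kwargs)
        a, b, f, g = fc.inputs_used
        rows.append(
            {"gene": gene, "method": fc.method, "fold": fc.fold,
             "A": a, "B": b, "F": f, "G": g}
        )
    return pd.DataFrame(rows, columns=["gene", "method", "fold", "A", "B", "F", "G"])
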