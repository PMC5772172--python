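"""Signature-matrix deconvolution of bulk profiles by linear nu-SVR.

A signature basis is a gene x cell-type matrix of linear-scale group
means over marker genes chosen one-vs-rest.  Cell-type fractions in a
bulk mixture are estimated by nu-support-vector regression with a
linear kernel: mixture and basis are z-scored over the shared genes,
the SVR is fit at each nu in a small grid, the fit with the lowest
root-mean-squared reconstruction error wins, negative coefficients are
truncated at zero and the remainder renormalized to sum to one.

The z-scoring makes the estimate invariant to positive rescaling of a
mixture column, so absolute library depth does not matter — only the
composition does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .containers import ExpressionDataset, SampleDesign, group_means
from .differential import anova_condition_test, bh_fdr, signed_fold_change

__all__ = ["SignatureBasis", "DeconvolutionResult", "build_signature_basis", "svr_fractions"]

DEFAULT_NUS = (0.25, 0.5, 0.75)


@dataclass
class SignatureBasis:
    """Gene x cell-type linear-scale reference matrix plus selection trace."""

    matrix: pd.DataFrame
    selection: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate cell-type columns in the basis")
        if (self.matrix.to_numpy() == 0).all(axis=1).any():
            raise ValueError("basis contains an all-zero gene row")
        if self.matrix.empty:
            raise ValueError("empty signature basis")

    @property
    def cell_types(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix.to_numpy()))


@dataclass
class DeconvolutionResult:
    """Estimated fractions plus per-sample fit diagnostics.

    ``fractions``: sample x cell-type, rows nonnegative summing to 1
    (all-zero rows mark failed fits, listed in ``failed``).
    """

    fractions: pd.DataFrame
    nu: pd.Series
    rmse: pd.Series
    reconstruction_r: pd.Series
    failed: list[str] = field(default_factory=list)


def build_signature_basis(
    ds: ExpressionDataset,
    design: SampleDesign,
    cell_types: Sequence[str],
    genes_per_type: int = 50,
    q_cut: float = 0.3,
) -> SignatureBasis:
    """Pick one-vs-rest marker genes per type and assemble the basis.

    Per cell type, genes are tested type-vs-rest (one-factor ANOVA over
    the two groups), filtered at BH q < ``q_cut`` and positive
    fold-change, ranked by fold-change, and the top ``genes_per_type``
    retained.  The basis holds linear-scale group means over the union
    of all selected genes (each gene once).
    """
    if ds.scale != "log2":
        raise ValueError("build_signature_basis expects log2-scale data")
    design.validate_for(ds)
    sub_tab = design.table.loc[ds.samples]
    for ct in cell_types:
        if (sub_tab["condition"] == ct).sum() < 2:
            raise ValueError(f"cell type {ct!r} needs at least 2 replicates")
    selection: dict[str, list[str]] = {}
    for ct in cell_types:
        labels = np.where(sub_tab["condition"] == ct, ct, "rest")
        ovr_design = SampleDesign(pd.DataFrame({"condition": labels}, index=sub_tab.index))
        stats = anova_condition_test(ds, ovr_design)
        q = bh_fdr(stats["p"])
        fc = signed_fold_change(ds, ovr_design, ct, "rest")
        cand = pd.DataFrame({"fc": fc, "q": q}, index=ds.genes)
        cand = cand[(cand["q"] < q_cut) & (cand["fc"] > 1)]
        if cand.empty:
            raise ValueError(f"no qualifying marker genes for cell type {ct!r}")
        cand = cand.sort_index().sort_values("fc", ascending=False, kind="mergesort")
        selection[ct] = list(cand.index[:genes_per_type])
    union: list[str] = []
    for ct in cell_types:
        union.extend(g for g in selection[ct] if g not in union)
    gm = group_means(ds.subset_features(union), design)[list(cell_types)]
    matrix = 2.0 ** gm  # linear scale
    return SignatureBasis(matrix=matrix, selection=selection)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def svr_fractions(
    mixture: ExpressionDataset,
    basis: SignatureBasis,
    nus: Sequence[float] = DEFAULT_NUS,
) -> DeconvolutionResult:
    """Estimate cell-type fractions in each mixture column by linear nu-SVR.

    The mixture is restricted to the basis genes (basis genes absent
    from the mixture are dropped from both sides with a warning).  Per
    sample: z-score the mixture vector, fit a linear nu-SVR of the
    sample on the z-scored basis for every nu, keep the fit with the
    lowest reconstruction RMSE, truncate negative coefficients at zero
    and renormalize to fractions summing to 1.  A sample whose
    coefficients are all nonpositive is flagged failed and reported as
    all-zero fractions.
    """
    if mixture.scale != "linear":
        mixture = mixture.to_linear()
    common = basis.genes.intersection(mixture.genes)
    missing = basis.genes.difference(mixture.genes)
    if len(missing):
        warnings.warn(
            f"{len(missing)} basis genes absent from the mixture; dropped from both",
            stacklevel=2,
        )
    if len(common) < len(basis.cell_types):
        raise ValueError("fewer shared genes than cell types; deconvolution underdetermined")
    B = basis.matrix.loc[common].to_numpy(dtype=float)
    # the basis is standardized globally (one mean and sd over all entries)
    # so the relative scale of the cell-type columns is preserved; the
    # single global factor cancels in the final renormalization
    X = (B - B.mean()) / B.std()
    mix = mixture.values.loc[common]

    frac_rows, nu_list, rmse_list, rcorr_list, failed = [], [], [], [], []
    for sample in mix.columns:
        y = _zscore(mix[sample].to_numpy(dtype=float))
        best = None
        for nu in nus:
            model = NuSVR(kernel="linear", nu=nu, C=1.0)
            model.fit(X, y)
            recon = model.predict(X)
            rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
            if best is None or rmse < best[1]:
                best = (nu, rmse, model.coef_.ravel().copy(), recon)
        nu, rmse, coef, recon = best
        coef = np.clip(coef, 0.0, None)
        total = coef.sum()
        if total <= 0:
            failed.append(sample)
            frac = np.zeros_like(coef)
        else:
            frac = coef / total
        frac_rows.append(frac)
        nu_list.append(nu)
        rmse_list.append(rmse)
        rcorr_list.append(float(np.corrcoef(recon, y)[0, 1]))
    fractions = pd.DataFrame(frac_rows, index=mix.columns, columns=basis.cell_types)
    return DeconvolutionResult(
        fractions=fractions,
        nu=pd.Series(nu_list, index=mix.columns, name="nu"),
        rmse=pd.Series(rmse_list, index=mix.columns, name="rmse"),
        reconstruction_r=pd.Series(rcorr_list, index=mix.columns, name="r"),
        failed=failed,
    )
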