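"""Phylogenetic generalized least squares under Brownian motion.

Relatedness between cultivars makes their copy numbers and chemotypes
non-independent observations: a plain regression treats a clade of
near-identical plants as many data points.  PGLS restores valid inference by
giving the regression an error covariance proportional to shared evolutionary
history.  Under Brownian motion the covariance of two tips equals the
root-to-tip path length they share, i.e. the depth of their most recent
common ancestor.

The module exposes the covariance construction, a GLS fit with t-based
inference, the CN-chemotype association table (corrected and uncorrected
statistics side by side), and the decarboxylation arithmetic that converts
acidic cannabinoid measurements to estimated totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import solve_triangular

from .depth import CopyNumberTable
from .errors import (
    ConditioningError,
    InsufficientDataError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

#: Molar-mass ratio of the neutral to the acidic cannabinoid form
#: (e.g. THC 314.5 g/mol vs THCA 358.5 g/mol): the fraction of acid mass
#: retained as neutral compound after decarboxylation.
DECARBOXYLATION_FACTOR = 0.877


@dataclass
class BMCovariance:
    """Brownian-motion trait covariance implied by a tree, over a fixed tip order."""

    tip_order: list[str]
    V: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.shape != (len(self.tip_order), len(self.tip_order)):
            raise InvalidInputError("covariance shape does not match tip order")
        if not np.allclose(V, V.T):
            raise InvalidInputError("covariance is not symmetric")
        self.V = V


@dataclass(frozen=True)
class PGLSFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    t_slope: float
    t_intercept: float
    p_slope: float
    p_intercept: float
    correlation_coefficient: float
    sigma2: float
    n: int


def bm_covariance(tree: dendropy.Tree, tips: list[str] | None = None) -> BMCovariance:
    """V[i, j] = depth of the MRCA of tips i and j (shared root-to-tip path).

    ``tips`` selects and orders a subset of leaf labels; by default all leaves
    in tree order.  Unknown labels raise a lookup error.
    """
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if tips is None:
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in leaves]
    if missing:
        raise KeyError(f"tips not on tree: {missing}")

    # root-to-node depth for every node
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        depth[id(node)] = (depth[id(node.parent_node)] if node.parent_node else 0.0) + edge

    # ancestor chains (as id sets) per requested tip
    chains: list[list] = []
    for t in tips:
        chain = []
        node = leaves[t]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains.append(chain)

    n = len(tips)
    V = np.zeros((n, n))
    for i in range(n):
        ancestors_i = {id(nd) for nd in chains[i]}
        V[i, i] = depth[id(chains[i][0])]
        for j in range(i + 1, n):
            mrca = next(nd for nd in chains[j] if id(nd) in ancestors_i)
            V[i, j] = V[j, i] = depth[id(mrca)]
    return BMCovariance(tip_order=list(tips), V=V)


def _solve_gls(V: np.ndarray) -> np.ndarray:
    """Cholesky factor of V, retrying once with a small ridge if V is singular."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.trace(V)
        logger.warning("covariance not positive definite; adding ridge %.3e", ridge)
        try:
            return np.linalg.cholesky(V + ridge * np.eye(V.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ConditioningError("covariance matrix is singular") from exc


def pgls_fit(y, x, V: BMCovariance | np.ndarray) -> PGLSFit:
    """GLS regression of y on x with error covariance proportional to V.

    beta = (X' V^-1 X)^-1 X' V^-1 y with an intercept column; standard errors
    from sigma^2 (X' V^-1 X)^-1 with sigma^2 = e' V^-1 e / (n - 2); two-sided
    p-values from t with n - 2 df.  ``correlation_coefficient`` is the
    sign-preserving square root of the GLS R^2 (residual GLS sum of squares
    relative to the GLS-weighted-mean-only model), so V = I reproduces the
    ordinary Pearson r.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Vm = V.V if isinstance(V, BMCovariance) else np.asarray(V, dtype=float)
    n = len(y)
    if len(x) != n or Vm.shape != (n, n):
        raise InvalidInputError("dimension mismatch between y, x and V")
    if n < 3:
        raise InvalidInputError("PGLS needs at least 3 observations")

    L = _solve_gls(Vm)
    # whiten: solve L z = v  =>  z' z = v' V^-1 v
    X = np.column_stack([np.ones(n), x])
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)

    XtX = Xw.T @ Xw
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("design matrix is singular (constant predictor?)") from exc
    beta = XtX_inv @ Xw.T @ yw
    resid = yw - Xw @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    # GLS R^2 against the weighted-mean-only model
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    ss_tot = float((yw - mu * ones_w) @ (yw - mu * ones_w))
    ss_res = float(resid @ resid)
    r2 = 0.0 if ss_tot <= 0 else max(0.0, 1.0 - ss_res / ss_tot)
    r = float(np.sign(beta[1]) * np.sqrt(min(r2, 1.0)))

    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=float(se[1]),
        intercept_se=float(se[0]),
        t_slope=float(tvals[1]),
        t_intercept=float(tvals[0]),
        p_slope=float(min(pvals[1], 1.0)),
        p_intercept=float(min(pvals[0], 1.0)),
        correlation_coefficient=r,
        sigma2=sigma2,
        n=n,
    )


def total_cannabinoid(
    neutral_pct: float, acid_pct: float, factor: float = DECARBOXYLATION_FACTOR
) -> float:
    """Estimated total cannabinoid percent: neutral + factor x acid.

    The factor is the molar-mass ratio lost to CO2 on decarboxylation
    (default 0.877 for THCA->THC and CBDA->CBD).
    """
    if neutral_pct < 0 or acid_pct < 0 or factor < 0:
        raise InvalidInputError("cannabinoid percentages and factor must be >= 0")
    return neutral_pct + factor * acid_pct


def match_chemotypes(
    samples: pd.DataFrame, chemotypes: pd.DataFrame, cannabinoid: str
) -> pd.Series:
    """Per-sample chemotype values for one cannabinoid (or "total").

    ``chemotypes`` rows carry (cultivar, cannabinoid, percent, provenance)
    where provenance is "individual" (cultivar column then holds a sample_id)
    or "average" (cultivar-level mean).  Individual values win over cultivar
    averages when both exist.  ``cannabinoid = "total"`` sums all measured
    cannabinoids per sample.  Samples without any value are absent from the
    result.
    """
    if cannabinoid == "total":
        per_compound = [
            match_chemotypes(samples, chemotypes, c)
            for c in sorted(chemotypes["cannabinoid"].unique())
        ]
        merged = pd.concat(per_compound, axis=1)
        return merged.dropna().sum(axis=1)

    chem = chemotypes[chemotypes["cannabinoid"] == cannabinoid]
    indiv = chem[chem["provenance"] == "individual"].set_index("cultivar")["percent"]
    avg = chem[chem["provenance"] == "average"].groupby("cultivar")["percent"].mean()
    out = {}
    for _, row in samples.iterrows():
        sid, cultivar = row["sample_id"], row["cultivar"]
        if sid in indiv.index:
            out[sid] = float(indiv.loc[sid])
        elif cultivar in avg.index:
            out[sid] = float(avg.loc[cultivar])
    return pd.Series(out, name=cannabinoid, dtype=float)


def correlate_cn_chemotype(
    cn_table: CopyNumberTable,
    chemotypes: pd.DataFrame,
    tree: dendropy.Tree,
    cannabinoid: str,
) -> pd.DataFrame:
    """Per-paralog association of CN with one cannabinoid, corrected and not.

    Each row holds the PGLS slope / correlation / p alongside the uncorrected
    Pearson r and p on the same matched samples, plus the provenance counts of
    the chemotype values used.  Requires >= 3 samples present in the CN table,
    the chemotype table and the tree.
    """
    chem_values = match_chemotypes(cn_table.samples, chemotypes, cannabinoid)
    tree_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    matched = [
        sid
        for sid in cn_table.values.index
        if sid in chem_values.index and sid in tree_tips
    ]
    if len(matched) < 3:
        unmatched = sorted(set(cn_table.values.index) - set(matched))
        raise InsufficientDataError(
            f"only {len(matched)} samples have CN, chemotype and tree placement; "
            f"unmatched: {unmatched}"
        )
    logger.info(
        "chemotype '%s': %d of %d samples matched", cannabinoid, len(matched),
        len(cn_table.values.index),
    )
    V = bm_covariance(tree, matched)
    y = chem_values.loc[matched].to_numpy()
    rows = []
    for paralog in cn_table.paralogs:
        x = cn_table.values.loc[matched, paralog].to_numpy()
        row: dict = {"paralog": paralog, "cannabinoid": cannabinoid, "n": len(matched)}
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            row.update(pgls_r=np.nan, pgls_p=np.nan, pgls_slope=np.nan,
                       pearson_r=np.nan, pearson_p=np.nan)
        else:
            fit = pgls_fit(y, x, V)
            pear_r, pear_p = sps.pearsonr(x, y)
            row.update(
                pgls_slope=fit.slope,
                pgls_r=fit.correlation_coefficient,
                pgls_p=fit.p_slope,
                pearson_r=float(pear_r),
                pearson_p=float(pear_p),
            )
        rows.append(row)
    return pd.DataFrame(rows)
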