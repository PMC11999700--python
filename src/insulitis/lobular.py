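"""Lobular patterning: lobule assignment, extra-islet lobular abundance, and
hierarchical linear models of islet pseudotime.

The models (R formula syntax):

* ICC (intercept-only):    pseudotime ~ 1 + (1 | lobule)
* two-level, per donor:    pseudotime ~ abundance + (1 | lobule)
* three-level, all donors: pseudotime ~ abundance + (1 + abundance | donor)
                                                  + (1 | lobule)

where ``abundance`` is the extra-islet count of a cell type in the islet's
lobule divided by the lobule's extra-islet acinar count, z-normalised within
donor, and pseudotime is z-normalised across the dataset.  Models are fitted
by restricted maximum likelihood with variance parameters on an
unconstrained (log / Cholesky) scale, and fixed-effect inference uses
Satterthwaite degrees of freedom computed from numerical derivatives of the
fixed-effect variance with respect to the variance parameters and the
observed REML information.

The intraclass correlation ICC = tau² / (tau² + sigma²) measures how much of
the islet pseudotime variance lies between lobules: 0 means islets within a
lobule vary as much as islets across the donor, 1 means lobules are
internally homogeneous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import t as t_dist
from shapely.strtree import STRtree

from .synthetic import LobulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "HLMFit", "LobularAbundance",
    "assign_lobules", "lobular_abundance",
    "fit_icc", "fit_two_level_hlm", "fit_three_level_hlm",
    "anova_moment_icc",
    "simulate_icc_data", "simulate_two_level", "simulate_three_level",
]

EDGE = LobulePartition.EDGE_LABEL


# ---------------------------------------------------------------------------
# lobule assignment and abundance


def assign_lobules(table: pd.DataFrame, partition: LobulePartition) -> pd.Series:
    """Lobule label per cell by point-in-polygon lookup; cells outside all
    polygons get the reserved "edge" label.  Boundary ties go to the lowest
    lobule id."""
    for poly in partition.polygons:
        if not poly.is_valid:
            raise ValueError("malformed lobule polygon")
    pts = shapely.points(table["x_um"].to_numpy(), table["y_um"].to_numpy())
    tree = STRtree(partition.polygons)
    labels = np.full(len(table), EDGE, dtype=object)
    hit_cell, hit_poly = tree.query(pts, predicate="intersects")
    order = np.lexsort((hit_poly, hit_cell))[::-1]
    for ci, pj in zip(hit_cell[order], hit_poly[order]):
        labels[ci] = partition.lobule_ids[pj]
    return pd.Series(labels, index=table.index, name="lobule_id")


@dataclass
class LobularAbundance:
    """Extra-islet lobular abundances plus per-lobule islet summaries."""

    raw: pd.DataFrame          # (donor_id, lobule_id) x cell type, count/acinar
    z: pd.DataFrame            # same shape, z-normalised within donor
    islets: pd.DataFrame       # islet_id, donor_id, lobule_id, pseudotime, pseudotime_z
    excluded_lobules: list = field(default_factory=list)


def lobular_abundance(
    table: pd.DataFrame,
    lobule_of_cell: pd.Series,
    islet_member_ids: np.ndarray,
    islet_meta: pd.DataFrame,
    pseudotime: pd.Series,
    islet_lobule: pd.Series,
    acinar_type: str = "Acinar",
    donor_col: str = "donor_id",
) -> LobularAbundance:
    """Lobule x cell-type abundance from extra-islet cells only.

    Abundance = count of the type / count of acinar cells, both restricted
    to the lobule's extra-islet cells.  Lobules with no extra-islet acinar
    cell, and the "edge" pseudo-lobule, are excluded from modelling (listed
    in ``excluded_lobules``).  Abundances are z-normalised within donor
    (across the donor's lobules); pseudotime is z-normalised across all
    islets.
    """
    is_member = table["cell_id"].isin(islet_member_ids).to_numpy()
    extra = table[~is_member].copy()
    extra["lobule_id"] = lobule_of_cell.loc[extra.index]

    counts = (extra.groupby([donor_col, "lobule_id"], observed=True)["cell_type"]
              .value_counts().unstack(fill_value=0))
    excluded = []
    rows = []
    for (donor, lob), row in counts.iterrows():
        if lob == EDGE:
            excluded.append((donor, lob, "edge"))
            continue
        n_acinar = row.get(acinar_type, 0)
        if n_acinar == 0:
            logger.warning("lobule %s/%s has no extra-islet acinar cells; excluded", donor, lob)
            excluded.append((donor, lob, "no-acinar"))
            continue
        rows.append(pd.Series(row / n_acinar, name=(donor, lob)))
    raw = pd.DataFrame(rows)
    raw.index = pd.MultiIndex.from_tuples(raw.index, names=[donor_col, "lobule_id"])

    z = raw.copy()
    for donor, idx in raw.groupby(level=0).groups.items():
        sub = raw.loc[idx]
        sd = sub.std(ddof=1)
        z.loc[idx] = (sub - sub.mean()) / sd.where(sd > 0, 1.0)

    pt = pseudotime.loc[islet_meta.index]
    pt_z = (pt - pt.mean()) / pt.std(ddof=1)
    islets = pd.DataFrame({
        "donor_id": islet_meta["donor_id"],
        "lobule_id": islet_lobule.loc[islet_meta.index],
        "pseudotime": pt,
        "pseudotime_z": pt_z,
    })
    return LobularAbundance(raw=raw, z=z, islets=islets, excluded_lobules=excluded)


def islet_lobule_assignment(islets, partition: LobulePartition) -> pd.Series:
    """Lobule of each islet by its centroid."""
    pts = shapely.points([i.centroid[0] for i in islets], [i.centroid[1] for i in islets])
    tree = STRtree(partition.polygons)
    labels = np.full(len(islets), EDGE, dtype=object)
    hit, poly = tree.query(pts, predicate="intersects")
    order = np.lexsort((poly, hit))[::-1]
    for ci, pj in zip(hit[order], poly[order]):
        labels[ci] = partition.lobule_ids[pj]
    return pd.Series(labels, index=[i.islet_id for i in islets], name="lobule_id")


# ---------------------------------------------------------------------------
# REML core

# Variance parameters live on an unconstrained working scale:
#   log sigma², then per term either log tau (scalar intercept variance) or
#   (log l11, l21, log l22) for an unstructured 2x2 Cholesky factor.
_LOGV_LO, _LOGV_HI = -12.0, 8.0


@dataclass
class _Block:
    n: int
    Syy: float
    Sxy: np.ndarray
    Sxx: np.ndarray
    Szz: np.ndarray
    Szx: np.ndarray
    Szy: np.ndarray
    term_cols: list[tuple[str, np.ndarray]]   # (kind, column indices into Z)


class _REML:
    """Profiled-out-nothing REML for block-diagonal mixed models where every
    random-effect design enters through per-block cross-products (Woodbury
    identity), so each criterion evaluation costs O(q³) per block."""

    def __init__(self, y, X, block_ids, Z_builders):
        """Z_builders: per block, list of (kind, Z_cols) with kind in
        {'scalar', 'unstr2'}; scalar terms may have any number of columns
        (shared variance), unstr2 exactly 2."""
        self.p = X.shape[1]
        self.blocks: list[_Block] = []
        self.kinds: list[str] = None
        for b, (yb, Xb, terms) in enumerate(zip(*_split_blocks(y, X, block_ids, Z_builders))):
            Z = np.hstack([Zc for _, Zc in terms]) if terms else np.zeros((len(yb), 0))
            cols = []
            start = 0
            kinds = []
            for kind, Zc in terms:
                idx = np.arange(start, start + Zc.shape[1])
                cols.append((kind, idx))
                kinds.append(kind)
                start += Zc.shape[1]
            if self.kinds is None:
                self.kinds = kinds
            self.blocks.append(_Block(
                n=len(yb), Syy=float(yb @ yb), Sxy=Xb.T @ yb, Sxx=Xb.T @ Xb,
                Szz=Z.T @ Z, Szx=Z.T @ Xb, Szy=Z.T @ yb, term_cols=cols))
        self.n_total = sum(b.n for b in self.blocks)
        self.n_theta = 1 + sum(1 if k == "scalar" else 3 for k in self.kinds)

    def _chol_G(self, block: _Block, theta) -> np.ndarray:
        q = block.Szz.shape[0]
        L = np.zeros((q, q))
        pos = 1
        for kind, idx in block.term_cols:
            if kind == "scalar":
                L[idx, idx] = math.exp(theta[pos])
                pos += 1
            else:  # unstr2
                a, c, b2 = theta[pos], theta[pos + 1], theta[pos + 2]
                i0, i1 = idx
                L[i0, i0] = math.exp(a)
                L[i1, i0] = c
                L[i1, i1] = math.exp(b2)
                pos += 3
        return L

    def _assemble(self, theta):
        sigma2 = math.exp(theta[0])
        logdet = 0.0
        A = np.zeros((self.p, self.p))
        bvec = np.zeros(self.p)
        quad = 0.0
        for blk in self.blocks:
            L = self._chol_G(blk, theta)
            q = L.shape[0]
            if q:
                # V = sigma² (I + Z L Lᵀ Zᵀ): sigma² factors out entirely
                W = np.eye(q) + L.T @ blk.Szz @ L
                cW = cho_factor(W, lower=True)
                logdetW = 2.0 * np.log(np.diag(cW[0])).sum()
                LtZx = L.T @ blk.Szx
                LtZy = L.T @ blk.Szy
                WinvZx = cho_solve(cW, LtZx)
                WinvZy = cho_solve(cW, LtZy)
                A_b = (blk.Sxx - LtZx.T @ WinvZx) / sigma2
                b_b = (blk.Sxy - LtZx.T @ WinvZy) / sigma2
                q_b = (blk.Syy - LtZy @ WinvZy) / sigma2
            else:
                logdetW = 0.0
                A_b = blk.Sxx / sigma2
                b_b = blk.Sxy / sigma2
                q_b = blk.Syy / sigma2
            logdet += blk.n * math.log(sigma2) + logdetW
            A += A_b
            bvec += b_b
            quad += q_b
        return sigma2, logdet, A, bvec, quad

    def neg2_reml(self, theta) -> float:
        try:
            _, logdet, A, bvec, quad = self._assemble(theta)
            cA = cho_factor(A, lower=True)
            logdetA = 2.0 * np.log(np.diag(cA[0])).sum()
            beta = cho_solve(cA, bvec)
            return logdet + logdetA + (quad - bvec @ beta)
        except np.linalg.LinAlgError:
            return 1e12

    def beta_cov(self, theta):
        _, _, A, bvec, _ = self._assemble(theta)
        cov = np.linalg.inv(A)
        return cov @ bvec, cov

    def fit(self, n_restarts: int = 5, tol: float = 1e-8):
        d = self.n_theta
        base = np.zeros(d)
        starts = [base]
        offsets = [-2.0, 2.0, -4.0, 1.0]
        for k in range(n_restarts - 1):
            s = base.copy()
            s[:] = offsets[k % len(offsets)] * (0.5 if k >= len(offsets) else 1.0)
            starts.append(s)
        bounds = []
        pos = 0
        for k in ["sigma"] + self.kinds:
            if k in ("sigma", "scalar"):
                bounds.append((_LOGV_LO, _LOGV_HI))
                pos += 1
            else:
                bounds.extend([(_LOGV_LO, _LOGV_HI), (-60.0, 60.0), (_LOGV_LO, _LOGV_HI)])
                pos += 3
        best = None
        for s in starts[:max(1, n_restarts)]:
            res = minimize(self.neg2_reml, s, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": tol, "gtol": 1e-8, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        return best

    # --- Satterthwaite machinery -------------------------------------

    def _var_beta_j(self, theta, j) -> float:
        _, _, A, _, _ = self._assemble(theta)
        return float(np.linalg.inv(A)[j, j])

    def satterthwaite_df(self, theta, j, rel_h: float = 1e-4) -> float:
        d = len(theta)
        h = rel_h * np.maximum(1.0, np.abs(theta))
        grad = np.zeros(d)
        for k in range(d):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            grad[k] = (self._var_beta_j(tp, j) - self._var_beta_j(tm, j)) / (2 * h[k])
        # observed information of theta from the -2 log REML criterion
        H = np.zeros((d, d))
        f0 = self.neg2_reml(theta)
        for a in range(d):
            for b in range(a, d):
                ta = theta.copy(); ta[a] += h[a]; ta[b] += h[b]
                tb = theta.copy(); tb[a] += h[a]; tb[b] -= h[b]
                tc = theta.copy(); tc[a] -= h[a]; tc[b] += h[b]
                td = theta.copy(); td[a] -= h[a]; td[b] -= h[b]
                H[a, b] = H[b, a] = (
                    self.neg2_reml(ta) - self.neg2_reml(tb)
                    - self.neg2_reml(tc) + self.neg2_reml(td)
                ) / (4 * h[a] * h[b])
        try:
            cov_theta = 2.0 * np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return float(self.n_total - self.p)
        var_j = self._var_beta_j(theta, j)
        denom = float(grad @ cov_theta @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n_total - self.p)
        df = 2.0 * var_j ** 2 / denom
        return float(np.clip(df, 1.0, 1e7))


def _split_blocks(y, X, block_ids, Z_builders):
    ys, Xs, terms = [], [], []
    for b in pd.unique(block_ids):
        mask = block_ids == b
        ys.append(y[mask])
        Xs.append(X[mask])
        terms.append(Z_builders(b, mask))
    return ys, Xs, terms


@dataclass
class HLMFit:
    """A fitted hierarchical linear model."""

    model: str
    fixed_effects: pd.DataFrame        # term, estimate, se, df, t, p
    variance_components: dict[str, float]
    icc: float | None
    converged: bool
    neg2_reml: float
    n_obs: int
    flags: list[str] = field(default_factory=list)

    @property
    def slope(self) -> float:
        return float(self.fixed_effects.set_index("term").loc["x", "estimate"])

    @property
    def slope_p(self) -> float:
        return float(self.fixed_effects.set_index("term").loc["x", "p"])


def _finish_fit(model_name, reml: _REML, res, terms_named, fe_names,
                icc_from=None, n_restarts_note=None) -> HLMFit:
    theta = res.x
    beta, cov = reml.beta_cov(theta)
    flags = []
    if not res.success:
        flags.append(f"optimizer: {res.message}")
    rows = []
    for j, name in enumerate(fe_names):
        se = math.sqrt(cov[j, j])
        df = reml.satterthwaite_df(theta, j)
        tval = beta[j] / se if se > 0 else np.nan
        p = float(2 * t_dist.sf(abs(tval), df)) if np.isfinite(tval) else np.nan
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append({"term": name, "estimate": float(beta[j]), "se": se,
                     "df": df, "t": float(tval), "p": p})
    sigma2 = math.exp(theta[0])
    vcs = {"sigma2": sigma2}
    pos = 1
    for kind, name in terms_named:
        if kind == "scalar":
            vcs[name] = math.exp(theta[pos]) ** 2 * sigma2
            pos += 1
        else:
            l11, l21, l22 = math.exp(theta[pos]), theta[pos + 1], math.exp(theta[pos + 2])
            vcs[f"{name}_intercept_var"] = l11 ** 2 * sigma2
            vcs[f"{name}_cov"] = l11 * l21 * sigma2
            vcs[f"{name}_slope_var"] = (l21 ** 2 + l22 ** 2) * sigma2
            pos += 3
    # boundary flags
    for k, v in vcs.items():
        if k != "sigma2" and v < 1e-8 * sigma2:
            flags.append(f"boundary: {k} ~ 0")
    icc = None
    if icc_from is not None:
        tau2 = vcs[icc_from]
        icc = tau2 / (tau2 + sigma2)
    return HLMFit(model=model_name, fixed_effects=pd.DataFrame(rows),
                  variance_components=vcs, icc=icc, converged=bool(res.success),
                  neg2_reml=float(res.fun), n_obs=reml.n_total, flags=flags)


# NOTE: random-effect scales are parametrised relative to sigma: the scalar
# working parameter is log(tau/sigma), hence tau² = exp(2·theta)·sigma².


def _lobule_Z(lobules_in_block):
    levels = pd.unique(lobules_in_block)
    idx = {l: i for i, l in enumerate(levels)}
    Z = np.zeros((len(lobules_in_block), len(levels)))
    Z[np.arange(len(lobules_in_block)), [idx[l] for l in lobules_in_block]] = 1.0
    return Z


def fit_icc(
    pseudotime: np.ndarray | pd.Series,
    lobule_ids: np.ndarray | pd.Series,
    min_islets_per_lobule: int = 2,
    n_restarts: int = 5,
) -> HLMFit:
    """Random-intercept model pseudotime ~ 1 + (1 | lobule); ICC =
    tau²/(tau²+sigma²).  Lobules with fewer than ``min_islets_per_lobule``
    islets are excluded."""
    y = np.asarray(pseudotime, dtype=float)
    lob = np.asarray(lobule_ids)
    sizes = pd.Series(lob).value_counts()
    keep_lobs = sizes[sizes >= min_islets_per_lobule].index
    mask = pd.Series(lob).isin(keep_lobs).to_numpy()
    y, lob = y[mask], lob[mask]
    if len(pd.unique(lob)) < 2:
        raise ValueError("need at least 2 lobules with enough islets for the ICC model")
    X = np.ones((len(y), 1))
    block = np.zeros(len(y), dtype=int)  # single block; lobule enters through Z

    def Z_builders(b, m):
        return [("scalar", _lobule_Z(lob))]

    reml = _REML(y, X, block, Z_builders)
    res = reml.fit(n_restarts=n_restarts)
    fit = _finish_fit("icc", reml, res, [("scalar", "tau2_lobule")],
                      ["intercept"], icc_from="tau2_lobule")
    if not np.isfinite(res.fun):
        raise RuntimeError(f"ICC model did not converge: {res.message}")
    return fit


def fit_two_level_hlm(
    y: np.ndarray | pd.Series,
    x_lobule: np.ndarray | pd.Series,
    lobule_ids: np.ndarray | pd.Series,
    n_restarts: int = 5,
) -> HLMFit:
    """Per-donor model pseudotime ~ abundance + (1 | lobule).

    ``x_lobule`` is the lobule-level covariate expanded per islet.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_lobule, dtype=float)
    lob = np.asarray(lobule_ids)
    if len(pd.unique(lob)) < 2:
        raise ValueError("random intercept inestimable with a single lobule")
    if np.ptp(x) == 0:
        raise ValueError("slope inestimable: covariate constant across lobules")
    X = np.column_stack([np.ones_like(y), x])
    block = np.zeros(len(y), dtype=int)

    def Z_builders(b, m):
        return [("scalar", _lobule_Z(lob))]

    reml = _REML(y, X, block, Z_builders)
    res = reml.fit(n_restarts=n_restarts)
    return _finish_fit("two-level", reml, res, [("scalar", "tau2_lobule")],
                       ["intercept", "x"])


def fit_three_level_hlm(
    y: np.ndarray | pd.Series,
    x_lobule: np.ndarray | pd.Series,
    lobule_ids: np.ndarray | pd.Series,
    donor_ids: np.ndarray | pd.Series,
    n_restarts: int = 5,
) -> HLMFit:
    """Three-level model pseudotime ~ abundance + (1 + abundance | donor)
    + (1 | lobule), with an unstructured donor-level intercept/slope
    covariance."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_lobule, dtype=float)
    lob = np.asarray(lobule_ids)
    don = np.asarray(donor_ids)
    if len(pd.unique(don)) < 3:
        raise ValueError("need at least 3 donors for the three-level model")
    if np.ptp(x) == 0:
        raise ValueError("slope inestimable: covariate constant")
    X = np.column_stack([np.ones_like(y), x])
    # lobules must be globally unique (nested in donor)
    lob_full = np.array([f"{d}::{l}" for d, l in zip(don, lob)], dtype=object)

    def Z_builders(b, m):
        Z_donor = np.column_stack([np.ones(m.sum()), x[m]])
        return [("unstr2", Z_donor), ("scalar", _lobule_Z(lob_full[m]))]

    reml = _REML(y, X, don, Z_builders)
    res = reml.fit(n_restarts=n_restarts)
    return _finish_fit("three-level", reml, res,
                       [("unstr2", "donor"), ("scalar", "tau2_lobule")],
                       ["intercept", "x"])


def anova_moment_icc(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way random-effects ANOVA moment estimator of the ICC
    (between-group variance over total), truncated to [0, 1]."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    sizes = df.groupby("g")["y"].count()
    means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    J = len(sizes)
    N = len(df)
    msb = float((sizes * (means - grand) ** 2).sum() / (J - 1))
    ssw = float(((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    msw = ssw / (N - J)
    n0 = (N - (sizes ** 2).sum() / N) / (J - 1)
    tau2 = max((msb - msw) / n0, 0.0)
    return tau2 / (tau2 + msw) if tau2 + msw > 0 else 0.0


# ---------------------------------------------------------------------------
# simulation helpers (the generative counterparts of the three models)


def simulate_icc_data(n_lobules, islets_per_lobule, icc, rng):
    """Balanced design with unit total variance split as tau²=icc,
    sigma²=1-icc.  Returns (y, lobule_ids)."""
    b = rng.normal(0, math.sqrt(icc), n_lobules)
    y = np.repeat(b, islets_per_lobule) + rng.normal(
        0, math.sqrt(1 - icc), n_lobules * islets_per_lobule)
    lob = np.repeat(np.arange(n_lobules), islets_per_lobule)
    return y, lob


def simulate_two_level(n_lobules, islets_per_lobule, gamma1, tau2, sigma2, rng):
    """y_ij = gamma1 * x_j + u_j + e_ij with x_j ~ N(0,1) per lobule.
    Returns (y, x expanded per islet, lobule_ids)."""
    x = rng.normal(0, 1, n_lobules)
    u = rng.normal(0, math.sqrt(tau2), n_lobules)
    lob = np.repeat(np.arange(n_lobules), islets_per_lobule)
    y = gamma1 * x[lob] + u[lob] + rng.normal(0, math.sqrt(sigma2), len(lob))
    return y, x[lob], lob


def simulate_three_level(n_donors, n_lobules, islets_per_lobule, gamma1,
                         slope_sd, tau2, sigma2, rng, intercept_sd=0.3):
    """Donor-level random intercept/slope plus lobule intercepts.
    Returns (y, x, lobule_ids, donor_ids)."""
    ys, xs, lobs, dons = [], [], [], []
    for d in range(n_donors):
        g0 = rng.normal(0, intercept_sd)
        g1 = gamma1 + rng.normal(0, slope_sd)
        x = rng.normal(0, 1, n_lobules)
        u = rng.normal(0, math.sqrt(tau2), n_lobules)
        lob = np.repeat(np.arange(n_lobules), islets_per_lobule)
        y = g0 + g1 * x[lob] + u[lob] + rng.normal(0, math.sqrt(sigma2), len(lob))
        ys.append(y)
        xs.append(x[lob])
        lobs.append(lob)
        dons.append(np.full(len(lob), d))
    return (np.concatenate(ys), np.concatenate(xs),
            np.concatenate(lobs), np.concatenate(dons))
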