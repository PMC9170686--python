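"""Sparse-design functional principal component analysis.

Estimates a mean function and covariance surface on a regular grid by
kernel smoothing of pooled observations (the PACE approach for sparse,
irregularly sampled longitudinal data), eigendecomposes the smoothed
covariance, and scores subjects by the conditional expectation of their
component scores given their sparse observations — the standard estimator
when per-subject integration is impossible.

Scores for a subject with observations :math:`y_i` at times :math:`t_i`:

.. math::

   \\hat\\xi_{ik} = \\lambda_k \\phi_k(t_i)^\\top
        (\\Phi_i \\Lambda \\Phi_i^\\top + \\sigma^2 I)^{-1} (y_i - \\mu(t_i))

Subjects with fewer observations than ``min_obs`` receive missing scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FPCAError(ValueError):
    pass


@dataclass
class FPCABasis:
    """Fitted basis: grid, mean, eigenfunctions (columns), eigenvalues."""

    grid: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray   # (n_grid, k), orthonormal w.r.t. grid measure
    eigenvalues: np.ndarray      # (k,), non-increasing
    sigma2: float
    fve: np.ndarray = field(default_factory=lambda: np.array([]))
    score_center: np.ndarray | None = None  # training-score means (bias removal)


def _gauss_smooth_1d(grid: np.ndarray, x: np.ndarray, y: np.ndarray,
                     w: np.ndarray, h: float) -> np.ndarray:
    """Nadaraya-Watson estimate of E[y|t] on ``grid`` with weights ``w``."""
    d = (grid[:, None] - x[None, :]) / h
    k = np.exp(-0.5 * d * d) * w[None, :]
    num = k @ y
    den = k.sum(axis=1)
    den[den == 0] = np.nan
    out = num / den
    # fill any empty regions by nearest finite value
    if np.isnan(out).any():
        idx = np.flatnonzero(~np.isnan(out))
        if idx.size == 0:
            return np.zeros_like(out)
        out = np.interp(np.arange(out.size), idx, out[idx])
    return out


def _gcv_bandwidth(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   candidates: np.ndarray) -> float:
    """Generalized cross-validation over bandwidth candidates, computed on
    the (weighted) binned data so the smoother matrix stays small."""
    best, best_h = np.inf, candidates[-1]
    for h in candidates:
        d = (x[:, None] - x[None, :]) / h
        k = np.exp(-0.5 * d * d) * w[None, :]
        den = k.sum(axis=1, keepdims=True)
        s = k / np.where(den == 0, 1.0, den)
        yhat = s @ y
        tr = np.trace(s)
        n = x.size
        denom = (1.0 - tr / n)
        if denom <= 1e-3:
            continue
        gcv = np.sum(w * (y - yhat) ** 2) / (w.sum() * denom ** 2)
        if gcv < best:
            best, best_h = gcv, h
    return best_h


class SparseFPCA:
    """PACE-style FPCA for sparse longitudinal signals.

    Parameters
    ----------
    n_components : cap on retained components (default 10).
    fve_threshold : keep the smallest number of components whose fraction
        of variance explained reaches this value (never more than
        ``n_components``).
    n_grid : evaluation grid size.
    min_obs : minimum observations a subject needs to receive scores
        (default 4, i.e. strictly more than 3 data points).
    bandwidth : kernel bandwidth in time units; ``None`` selects one by GCV.
    """

    def __init__(self, n_components: int = 10, fve_threshold: float = 0.99,
                 n_grid: int = 51, min_obs: int = 4,
                 bandwidth: float | None = None, domain: tuple | None = None):
        self.n_components = n_components
        self.fve_threshold = fve_threshold
        self.n_grid = n_grid
        self.min_obs = min_obs
        self.bandwidth = bandwidth
        self.domain = domain
        self.basis_: FPCABasis | None = None

    # ------------------------------------------------------------------ fit
    def fit(self, ids: np.ndarray, times: np.ndarray, values: np.ndarray) -> "SparseFPCA":
        ids = np.asarray(ids)
        t = np.asarray(times, float)
        y = np.asarray(values, float)
        ok = np.isfinite(t) & np.isfinite(y)
        ids, t, y = ids[ok], t[ok], y[ok]
        uniq, inv, counts = np.unique(ids, return_inverse=True, return_counts=True)
        if int((counts >= self.min_obs).sum()) < 2:
            raise FPCAError("need at least 2 subjects with enough observations")
        keep = counts[inv] >= self.min_obs
        ids, t, y = ids[keep], t[keep], y[keep]

        lo, hi = self.domain if self.domain else (t.min(), t.max())
        if hi <= lo:
            hi = lo + 1.0
        grid = np.linspace(lo, hi, self.n_grid)
        dt = grid[1] - grid[0]

        # bin pooled observations to the grid
        bins = np.clip(np.round((t - lo) / dt).astype(int), 0, self.n_grid - 1)
        cnt = np.bincount(bins, minlength=self.n_grid).astype(float)
        ysum = np.bincount(bins, weights=y, minlength=self.n_grid)
        with np.errstate(invalid="ignore"):
            ybar = np.where(cnt > 0, ysum / np.maximum(cnt, 1), np.nan)

        rng_span = hi - lo
        if self.bandwidth is None:
            cands = rng_span * np.array([0.05, 0.08, 0.12, 0.18, 0.25])
            have = cnt > 0
            h = _gcv_bandwidth(grid[have], ybar[have], cnt[have], cands)
        else:
            h = float(self.bandwidth)
        have = cnt > 0
        mean = _gauss_smooth_1d(grid, grid[have], ybar[have], cnt[have], h)

        # centered residuals
        resid = y - np.interp(t, grid, mean)

        # raw covariance accumulated on the grid, off-diagonal pairs only
        order = np.argsort(ids, kind="stable")
        ids_o, bins_o, res_o = ids[order], bins[order], resid[order]
        starts = np.flatnonzero(np.r_[True, ids_o[1:] != ids_o[:-1]])
        ends = np.r_[starts[1:], ids_o.size]
        counts = ends - starts
        # all within-subject index pairs, built without a per-subject loop
        rep = np.repeat(counts, counts)            # partners per element
        rows = np.repeat(np.arange(ids_o.size), rep)
        seg_start = np.repeat(starts, counts)       # subject offset per element
        block_start = np.cumsum(rep) - rep
        within = np.arange(rep.sum()) - np.repeat(block_start, rep)
        cols = np.repeat(seg_start, rep) + within
        offdiag = rows != cols
        rows, cols = rows[offdiag], cols[offdiag]
        flat = bins_o[rows] * self.n_grid + bins_o[cols]
        csum = np.bincount(flat, weights=res_o[rows] * res_o[cols],
                           minlength=self.n_grid ** 2).reshape(self.n_grid, -1)
        ccnt = np.bincount(flat, minlength=self.n_grid ** 2).reshape(
            self.n_grid, -1).astype(float)

        # separable Gaussian smoothing of the covariance surface
        hc = 1.5 * h
        d = (grid[:, None] - grid[None, :]) / hc
        kw = np.exp(-0.5 * d * d)
        num = kw @ csum @ kw.T
        den = kw @ ccnt @ kw.T
        cov = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
        cov = 0.5 * (cov + cov.T)

        # measurement-error variance from the raw diagonal vs smooth surface
        sq = resid ** 2
        var_t = _gauss_smooth_1d(grid, t, sq, np.ones_like(sq), h)
        mid = slice(self.n_grid // 4, 3 * self.n_grid // 4)
        sigma2 = float(max(np.mean(var_t[mid] - np.diag(cov)[mid]), 1e-6))

        evals, evecs = np.linalg.eigh(cov)
        idx = np.argsort(evals)[::-1]
        evals, evecs = evals[idx], evecs[:, idx]
        pos = evals > max(1e-12, 1e-9 * max(evals.max(), 0.0))
        evals, evecs = evals[pos], evecs[:, pos]
        lam = evals * dt
        phi = evecs / np.sqrt(dt)

        if lam.size == 0:
            lam = np.array([0.0])
            phi = np.ones((self.n_grid, 1)) / np.sqrt(rng_span)
            fve = np.array([1.0])
            k = 1
        else:
            fve = np.cumsum(lam) / lam.sum()
            k = int(np.searchsorted(fve, self.fve_threshold) + 1)
            k = min(k, self.n_components, lam.size)
        self.basis_ = FPCABasis(grid=grid, mean=mean, eigenfunctions=phi[:, :k],
                                eigenvalues=lam[:k], sigma2=sigma2, fve=fve)
        # center scores on their training means: conditional-expectation
        # scores inherit any residual mean-smoothing bias as a common offset
        raw = self.score(ids, t, y)
        self.basis_.score_center = np.nan_to_num(
            np.nanmean(raw.to_numpy(), axis=0), nan=0.0)
        return self

    # ---------------------------------------------------------------- score
    def score(self, ids: np.ndarray, times: np.ndarray, values: np.ndarray,
              index: np.ndarray | None = None) -> pd.DataFrame:
        """Conditional-expectation scores, one row per subject in ``index``
        (default: subjects present in ``ids``); rows below ``min_obs``
        observations are all-NaN."""
        if self.basis_ is None:
            raise FPCAError("fit before scoring")
        b = self.basis_
        k = b.eigenvalues.size
        ids = np.asarray(ids)
        t = np.asarray(times, float)
        y = np.asarray(values, float)
        ok = np.isfinite(t) & np.isfinite(y)
        ids, t, y = ids[ok], t[ok], y[ok]
        resid = y - np.interp(t, b.grid, b.mean)
        phi_t = np.empty((t.size, k))
        for j in range(k):
            phi_t[:, j] = np.interp(t, b.grid, b.eigenfunctions[:, j])

        if index is None:
            index = np.unique(ids)
        index = np.asarray(index)
        out = np.full((index.size, k), np.nan)
        row_of = {v: i for i, v in enumerate(index)}

        order = np.argsort(ids, kind="stable")
        ids_o, res_o, phi_o = ids[order], resid[order], phi_t[order]
        starts = np.flatnonzero(np.r_[True, ids_o[1:] != ids_o[:-1]])
        ends = np.r_[starts[1:], ids_o.size]
        lam = b.eigenvalues
        groups: dict[int, list] = {}
        for s, e in zip(starts, ends):
            m = e - s
            if m < self.min_obs or ids_o[s] not in row_of:
                continue
            groups.setdefault(m, []).append((s, e))
        for m, spans in groups.items():
            g = len(spans)
            phi_b = np.empty((g, m, k))
            res_b = np.empty((g, m))
            rows = np.empty(g, dtype=int)
            for i, (s, e) in enumerate(spans):
                phi_b[i] = phi_o[s:e]
                res_b[i] = res_o[s:e]
                rows[i] = row_of[ids_o[s]]
            sigma = phi_b @ (lam[:, None] * phi_b.transpose(0, 2, 1)) \
                + b.sigma2 * np.eye(m)[None]
            sol = np.linalg.solve(sigma, res_b[..., None])[..., 0]
            out[rows] = (phi_b.transpose(0, 2, 1) @ sol[..., None])[..., 0] * lam
        if b.score_center is not None:
            out = out - b.score_center[None, :]
        cols = [f"fpc{j + 1}" for j in range(k)]
        return pd.DataFrame(out, index=index, columns=cols)

    def fit_score(self, ids, times, values, index=None) -> pd.DataFrame:
        return self.fit(ids, times, values).score(ids, times, values, index=index)
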