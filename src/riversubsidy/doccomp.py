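"""Dissolved-organic-carbon composition analytics.

Fluorescence excitation-emission matrices (EEMs), absorbance spectra and
size-exclusion chromatography (SEC) fractions together describe the quality
of DOC in a water sample. This module provides:

* a sample x excitation x emission tensor container and a PARAFAC
  alternating-least-squares decomposition separating the EEM set into
  trilinear fluorescent components (sample scores carry absolute intensity;
  spectral modes are normalised to unit maximum),
* classic optical indices — humification index (HIX, Ohno normalised
  variant), fluorescence index (FIX), freshness index beta:alpha, SUVA254
  and E2:E3,
* SEC size-fraction summaries (humic substances, high- and low-molecular-
  weight substances),
* z-scoring, PCA via SVD, and the multivariate trajectory statistic: the
  summed Euclidean path length of each sample unit through full PC space
  over time, a scalar measure of how much its DOC composition turned over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "EEMTensor",
    "ParafacModel",
    "OpticalIndices",
    "SECFractions",
    "parafac_als",
    "explained_variance",
    "tucker_congruence",
    "match_components",
    "optical_indices",
    "zscore_features",
    "pca",
    "PCAResult",
    "trajectory_path_length",
    "sec_summary",
    "mask_scatter_bands",
]


@dataclass
class EEMTensor:
    """Raman-normalised fluorescence intensities, sample x ex x em."""

    data: np.ndarray
    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.excitation_nm = np.asarray(self.excitation_nm, dtype=float)
        self.emission_nm = np.asarray(self.emission_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (sample, excitation, emission)")
        if self.data.shape[1] != self.excitation_nm.size:
            raise ValueError("excitation grid does not match data")
        if self.data.shape[2] != self.emission_nm.size:
            raise ValueError("emission grid does not match data")
        for g in (self.excitation_nm, self.emission_nm):
            if np.any(np.diff(g) <= 0):
                raise ValueError("wavelength grids must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass
class ParafacModel:
    """Trilinear decomposition X ~= sum_r scores_r o ex_r o em_r.

    Spectral loadings (``excitation``, ``emission``) are normalised to unit
    maximum; the absolute fluorescence magnitude sits in ``scores`` so the
    sample mode remains quantitatively comparable across samples.
    """

    scores: np.ndarray        # (n_samples, R)
    excitation: np.ndarray    # (n_ex, R)
    emission: np.ndarray      # (n_em, R)
    explained_variance_pct: float
    n_iter: int
    converged: bool
    fit_history: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.scores, self.excitation, self.emission)


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _ls_update(unfolded: np.ndarray, kr: np.ndarray, nonneg: bool) -> np.ndarray:
    """Solve factor @ kr.T ~= unfolded for one mode, optionally row-wise NNLS."""
    if not nonneg:
        sol, *_ = np.linalg.lstsq(kr, unfolded.T, rcond=None)
        return sol.T
    out = np.empty((unfolded.shape[0], kr.shape[1]))
    for i in range(unfolded.shape[0]):
        out[i], _ = nnls(kr, unfolded[i])
    return out


def parafac_als(
    eems: EEMTensor,
    R: int,
    nonneg: bool = True,
    tol: float = 1e-8,
    max_iter: int = 2500,
    n_starts: int = 10,
    seed: int = 0,
) -> ParafacModel:
    """PARAFAC by alternating least squares, best of ``n_starts`` restarts.

    Minimises ||X - sum_r a_r o b_r o c_r||^2 by cycling exact
    least-squares updates of the sample, excitation and emission factors
    (row-wise NNLS when ``nonneg``); each update cannot increase the
    objective, so the fit trace is monotone non-increasing — asserted every
    iteration. Convergence is a relative fit change below ``tol``.
    Deterministic for a given seed.
    """
    x = eems.data
    if np.any(~np.isfinite(x)):
        raise ValueError("tensor contains non-finite values; preprocess first")
    if R > min(x.shape):
        raise ValueError("R exceeds the smallest tensor dimension")
    rng = np.random.default_rng(seed)
    norm_x2 = float(np.sum(x * x))
    if norm_x2 == 0:
        raise ValueError("zero tensor")
    unf = [_unfold(x, m) for m in range(3)]

    def _hosvd_start():
        # leading singular vectors of each unfolding: a deterministic start
        # that sits near the dominant trilinear subspace
        facs = []
        for m in range(3):
            u, _, _ = np.linalg.svd(unf[m], full_matrices=False)
            f = u[:, :R].copy()
            if f.shape[1] < R:
                f = np.hstack([f, rng.standard_normal((f.shape[0], R - f.shape[1]))])
            facs.append(np.abs(f) if nonneg else f)
        return facs

    best = None
    traces = []
    for start in range(n_starts):
        if start == 0:
            factors = _hosvd_start()
        else:
            factors = [np.abs(rng.standard_normal((x.shape[m], R))) for m in range(3)]
        prev = np.inf
        history = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            for m in range(3):
                others = [factors[j] for j in range(3) if j != m]
                kr = _khatri_rao(others[0], others[1])
                factors[m] = _ls_update(unf[m], kr, nonneg)
            kr = _khatri_rao(factors[1], factors[2])
            resid = unf[0] - factors[0] @ kr.T
            sse = float(np.sum(resid * resid))
            # exact LS updates cannot increase the objective; allow only
            # float round-off at the noise floor of a (near-)exact fit
            assert sse <= prev * (1 + 1e-9) + 1e-12 * norm_x2, "ALS objective increased"
            history.append(sse)
            if np.isfinite(prev) and prev - sse <= tol * max(prev, 1e-300):
                converged = True
                prev = sse
                break
            prev = sse
        traces.append(np.array(history))
        if best is None or prev < best[0]:
            best = (prev, [f.copy() for f in factors], it, converged, np.array(history))
    sse, factors, n_iter, converged, history = best
    if not np.isfinite(sse):
        raise RuntimeError(f"ALS failed in all starts; fit traces: {traces}")
    a, b, c = factors
    # move spectral magnitude into the sample mode
    for spec in (b, c):
        m = np.max(np.abs(spec), axis=0)
        m[m == 0] = 1.0
        a *= m
        spec /= m
    ev = 100.0 * (1.0 - sse / norm_x2)
    return ParafacModel(
        scores=a, excitation=b, emission=c,
        explained_variance_pct=ev, n_iter=n_iter,
        converged=converged, fit_history=history,
    )


def explained_variance(model: ParafacModel, eems: EEMTensor) -> float:
    """Percent of tensor sum-of-squares captured: 100*(1 - ||X-Xhat||^2/||X||^2)."""
    x = eems.data
    norm2 = float(np.sum(x * x))
    if norm2 == 0:
        raise ValueError("zero-norm tensor")
    resid = x - model.reconstruct()
    return 100.0 * (1.0 - float(np.sum(resid * resid)) / norm2)


def tucker_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two loading vectors (Tucker's phi)."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def match_components(
    model: ParafacModel, true_ex: np.ndarray, true_em: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Permute model components to best match reference spectra.

    Components are matched by maximising summed excitation+emission Tucker
    congruence with the Hungarian assignment; returns (permutation,
    per-component mean congruence). Handles the inherent permutation
    ambiguity of trilinear models before any recovery comparison.
    """
    from scipy.optimize import linear_sum_assignment

    r = model.n_components
    if true_ex.shape[1] != r:
        raise ValueError("component count mismatch")
    cong = np.zeros((r, r))
    for i in range(r):
        for j in range(r):
            cong[i, j] = 0.5 * (
                tucker_congruence(model.excitation[:, i], true_ex[:, j])
                + tucker_congruence(model.emission[:, i], true_em[:, j])
            )
    rows, cols = linear_sum_assignment(-cong)
    perm = np.empty(r, dtype=int)
    perm[cols] = rows
    return perm, cong[rows, cols][np.argsort(cols)]


# ---------------------------------------------------------------------------
# optical indices

_HIX_EM_HUMIC = (435.0, 480.0)
_HIX_EM_FRESH = (300.0, 345.0)


def _band_integral(grid: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    m = (grid >= lo) & (grid <= hi)
    if m.sum() < 2:
        raise ValueError(f"band {lo}-{hi} nm not covered by grid")
    return float(np.trapezoid(values[m], grid[m]))


def _interp_at(grid: np.ndarray, values: np.ndarray, wl: float) -> float:
    if not grid[0] <= wl <= grid[-1]:
        raise ValueError(f"{wl} nm outside spectral coverage")
    return float(np.interp(wl, grid, values))


@dataclass
class OpticalIndices:
    """Per-sample optical proxies for DOM character.

    HIX: humification (Ohno normalised, in [0, 1]); FIX: microbial vs
    terrestrial source; beta_alpha: freshness (recent autochthonous
    production); SUVA254: aromaticity, l mg-C^-1 m^-1; E2E3: inverse proxy
    of molecular size.
    """

    hix: float = np.nan
    fix: float = np.nan
    beta_alpha: float = np.nan
    suva254: float = np.nan
    e2e3: float = np.nan


def optical_indices(
    absorbance_nm: np.ndarray | None,
    absorbance_m1: np.ndarray | None,
    emission_nm: np.ndarray | None,
    eem_sample: np.ndarray | None,
    excitation_nm: np.ndarray | None,
    doc_mgL: float | None = None,
) -> OpticalIndices:
    """Compute the five optical indices for one sample.

    Fluorescence indices are read off emission slices of the sample's EEM
    (ex 254 nm for HIX, 370 for FIX, 310 for beta:alpha; nearest-neighbour
    on the excitation grid, trapezoids on the native emission grid).
    Absorbance gives SUVA254 = a(254)/DOC and E2:E3 = a(250)/a(365).
    Indices whose inputs are missing come back NaN with a warning.
    """
    out = OpticalIndices()

    def em_slice(ex_target: float) -> np.ndarray:
        i = int(np.argmin(np.abs(excitation_nm - ex_target)))
        if abs(excitation_nm[i] - ex_target) > 10:
            raise ValueError(f"no excitation near {ex_target} nm")
        return eem_sample[i]

    if eem_sample is not None and emission_nm is not None and excitation_nm is not None:
        try:
            s254 = em_slice(254.0)
            humic = _band_integral(emission_nm, s254, *_HIX_EM_HUMIC)
            fresh = _band_integral(emission_nm, s254, *_HIX_EM_FRESH)
            out.hix = humic / (humic + fresh) if humic + fresh > 0 else np.nan
        except ValueError as e:
            warn(f"HIX unavailable: {e}", stacklevel=2)
        try:
            s370 = em_slice(370.0)
            out.fix = _interp_at(emission_nm, s370, 470.0) / _interp_at(emission_nm, s370, 520.0)
        except ValueError as e:
            warn(f"FIX unavailable: {e}", stacklevel=2)
        try:
            s310 = em_slice(310.0)
            m = (emission_nm >= 420.0) & (emission_nm <= 435.0)
            if not m.any():
                raise ValueError("420-435 nm emission band missing")
            out.beta_alpha = _interp_at(emission_nm, s310, 380.0) / float(np.max(s310[m]))
        except ValueError as e:
            warn(f"beta:alpha unavailable: {e}", stacklevel=2)
    else:
        warn("EEM inputs missing: fluorescence indices set to NaN", stacklevel=2)

    if absorbance_nm is not None and absorbance_m1 is not None:
        try:
            a254 = _interp_at(absorbance_nm, absorbance_m1, 254.0)
            if doc_mgL is not None and doc_mgL > 0:
                out.suva254 = a254 / doc_mgL
            else:
                warn("DOC missing: SUVA254 set to NaN", stacklevel=2)
            out.e2e3 = _interp_at(absorbance_nm, absorbance_m1, 250.0) / _interp_at(
                absorbance_nm, absorbance_m1, 365.0
            )
        except ValueError as e:
            warn(f"absorbance indices unavailable: {e}", stacklevel=2)
    else:
        warn("absorbance missing: SUVA254/E2:E3 set to NaN", stacklevel=2)
    return out


def hix_zsolnay(emission_nm: np.ndarray, em_slice_254: np.ndarray) -> float:
    """Unnormalised humification index: area(435-480)/area(300-345) at ex 254."""
    humic = _band_integral(emission_nm, em_slice_254, *_HIX_EM_HUMIC)
    fresh = _band_integral(emission_nm, em_slice_254, *_HIX_EM_FRESH)
    if fresh == 0:
        raise ValueError("zero 300-345 nm band")
    return humic / fresh


# ---------------------------------------------------------------------------
# multivariate trajectory analysis

def zscore_features(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to mean 0, sd 1 (ddof=1); drop constant columns."""
    if len(table) < 2:
        raise ValueError("need >= 2 rows")
    if not np.all(np.isfinite(table.to_numpy(dtype=float))):
        raise ValueError("non-finite values in feature table")
    sd = table.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if len(constant) == len(table.columns):
        raise ValueError("all columns constant: nothing to scale")
    if constant:
        warn(f"dropping constant columns: {constant}", stacklevel=2)
        table = table.drop(columns=constant)
        sd = sd.drop(constant)
    return (table - table.mean()) / sd


@dataclass
class PCAResult:
    scores: np.ndarray            # (n, r)
    loadings: np.ndarray          # (p, r), orthonormal columns
    variance_pct: np.ndarray      # (r,), sums to 100 over all retained axes
    columns: list[str]


def pca(scaled: pd.DataFrame | np.ndarray) -> PCAResult:
    """Principal components of a z-scored table via SVD.

    Retains every axis with nonzero singular value (rank-deficient input is
    truncated); sign convention: the largest-magnitude loading on each axis
    is positive. With all axes kept, the score space is an isometric
    rotation of the feature space.
    """
    if isinstance(scaled, pd.DataFrame):
        cols = list(scaled.columns)
        x = scaled.to_numpy(dtype=float)
    else:
        x = np.asarray(scaled, dtype=float)
        cols = [f"x{i}" for i in range(x.shape[1])]
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    for i in range(vt.shape[0]):  # deterministic signs
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    var = s**2
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        variance_pct=100.0 * var / var.sum(),
        columns=cols,
    )


def trajectory_path_length(
    scores: np.ndarray,
    groups: np.ndarray,
    order: np.ndarray,
    treatments: np.ndarray | None = None,
) -> tuple[dict, dict]:
    """Summed Euclidean path length per group through multivariate space.

    For each group (e.g. one mesocosm), points are sorted by ``order``
    (e.g. week) and consecutive Euclidean distances in the full score space
    are summed — the total compositional turnover from start to end of the
    experiment. With all PCs retained this equals the path length in the
    z-scored feature space (rotation isometry). Returns
    ``(per_group, per_treatment_mean)``; a single-point group gets length 0
    with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    order = np.asarray(order)
    lengths: dict = {}
    tre: dict = {}
    for g in pd.unique(groups):
        m = groups == g
        idx = np.argsort(order[m], kind="stable")
        pts = scores[m][idx]
        if len(pts) < 2:
            warn(f"group {g!r} has a single time point: path length 0", stacklevel=2)
            lengths[g] = 0.0
        else:
            lengths[g] = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if treatments is not None:
            tre.setdefault(treatments[m][0], []).append(lengths[g])
    means = {t: float(np.mean(v)) for t, v in sorted(tre.items())} if treatments is not None else {}
    return lengths, means


# ---------------------------------------------------------------------------
# SEC fractions

@dataclass
class SECFractions:
    """Size-exclusion chromatography summary for one sample."""

    hmws: float
    hs: float
    lmws: float
    hmws_pct: float
    hs_pct: float
    lmws_pct: float
    hmws_cn: float


def sec_summary(hmws: float, hs: float, lmws: float, hmws_c: float = np.nan, hmws_n: float = np.nan) -> SECFractions:
    """Percentages of summed size fractions plus the C:N of the HMWS pool."""
    for v in (hmws, hs, lmws):
        if v < 0:
            raise ValueError("fraction concentrations must be non-negative")
    total = hmws + hs + lmws
    if total == 0:
        raise ValueError("zero total: percentages undefined")
    cn = hmws_c / hmws_n if np.isfinite(hmws_c) and np.isfinite(hmws_n) and hmws_n > 0 else np.nan
    return SECFractions(
        hmws=hmws, hs=hs, lmws=lmws,
        hmws_pct=100.0 * hmws / total,
        hs_pct=100.0 * hs / total,
        lmws_pct=100.0 * lmws / total,
        hmws_cn=cn,
    )


def mask_scatter_bands(
    eem: np.ndarray,
    excitation_nm: np.ndarray,
    emission_nm: np.ndarray,
    width_nm: float = 15.0,
) -> np.ndarray:
    """Excise first/second-order Rayleigh scatter ridges and interpolate.

    Intended for synthetic EEMs only; real instrument corrections (Raman
    normalisation, inner-filter) are assumed done upstream. Bands of
    ``width_nm`` around em = ex and em = 2*ex are replaced by linear
    interpolation along the emission axis.
    """
    out = eem.copy()
    em = emission_nm
    for i, ex in enumerate(excitation_nm):
        bad = (np.abs(em - ex) < width_nm) | (np.abs(em - 2 * ex) < width_nm)
        if bad.any() and (~bad).sum() >= 2:
            out[i, bad] = np.interp(em[bad], em[~bad], out[i, ~bad])
    return out
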