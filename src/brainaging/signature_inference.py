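"""De novo mutational-signature extraction and burden-age regression.

Signatures are extracted from per-cell 96-channel spectra by non-negative
matrix factorization minimizing the generalized Kullback-Leibler
divergence with multiplicative updates; the factorization rank is chosen
by balancing restart-to-restart stability of the signatures against the
drop in reconstruction error, mirroring the usual practice of de novo
signature tools. Per-cell exposures (mutation-count units) are obtained
by nonnegative least squares against fixed, column-stochastic signatures,
and per-component clock rates come from ordinary least squares of
exposure on donor age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DataError
from .mutation_spectra import Spectrum96, cosine_sim

_EPS = 1e-10


@dataclass
class SignatureSet:
    """NMF result: column-stochastic signatures and per-cell exposures."""

    signatures: np.ndarray  # 96 x k, columns sum to 1
    exposures: np.ndarray  # k x n_cells, mutation-count units
    recon_error: float
    k: int
    restart_stability: float = 1.0
    objective_trace: np.ndarray | None = None

    def tc_mass(self) -> np.ndarray:
        """Per-signature mass on the T>C substitution class."""
        return self.signatures[64:80, :].sum(axis=0)

    def a1_a2_order(self) -> np.ndarray:
        """Column order labeling the T>C-dominant signature A1, the other(s) after.

        With k=2 this returns [A1 column, A2 column]; ties break by index.
        """
        return np.argsort(-self.tc_mass(), kind="stable")

    def to_frames(self, cell_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
        order = self.a1_a2_order()
        names = [f"A{i + 1}" for i in range(self.k)]
        from .mutation_spectra import CONTEXT_LABELS

        sig = pd.DataFrame(self.signatures[:, order], index=list(CONTEXT_LABELS), columns=names)
        cols = cell_ids if cell_ids is not None else range(self.exposures.shape[1])
        exp = pd.DataFrame(self.exposures[order, :], index=names, columns=list(cols))
        return sig, exp


@dataclass
class RegressionFit:
    """OLS fit of a per-cell quantity on donor age."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def spectra_matrix(per_cell_spectra: dict[str, Spectrum96]) -> tuple[np.ndarray, list[str]]:
    """Stack per-cell spectra into a 96 x n matrix (stable cell order)."""
    cells = list(per_cell_spectra)
    V = np.column_stack([per_cell_spectra[c].counts for c in cells])
    return V, cells


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div - V.sum() + WH.sum())


def _mu_kl_nmf(V, k, rng, n_iter, tol, W0=None, H0=None):
    m, n = V.shape
    W = rng.random((m, k)) + 0.1 if W0 is None else W0.copy()
    H = rng.random((k, n)) + 0.1 if H0 is None else H0.copy()
    trace = []
    ones = np.ones_like(V)
    prev = None
    for it in range(n_iter):
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(ones @ H.T, _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.T @ ones, _EPS)
        if it % 10 == 0 or it == n_iter - 1:
            obj = _kl_divergence(V, np.maximum(W @ H, _EPS))
            trace.append(obj)
            if prev is not None and abs(prev - obj) <= tol * max(abs(prev), 1.0):
                break
            prev = obj
    return W, H, np.array(trace)


def _normalize(W, H):
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    return W / scale, H * scale[:, None]


def nmf_decompose(
    spectra: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    n_iter: int = 500,
    tol: float = 1e-7,
    _warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> SignatureSet:
    """Best-of-restarts KL-NMF of a 96 x n spectra matrix.

    Signatures are column-normalized with the scale folded into the
    exposures; the per-iteration objective trace of the winning restart is
    retained (it is non-increasing up to the convergence tolerance).
    """
    V = np.asarray(spectra, dtype=float)
    if V.ndim != 2 or V.shape[0] != 96:
        raise ConfigError(f"spectra must be 96 x n_cells, got {V.shape}")
    if np.any(V < 0):
        raise DataError("spectra must be nonnegative")
    n = V.shape[1]
    if k <= 0 or k > min(96, n):
        raise ConfigError(f"rank k={k} outside [1, min(96, n_cells={n})]")

    ss = np.random.SeedSequence((seed, k))
    streams = [np.random.default_rng(s) for s in ss.spawn(n_restarts)]
    runs = []  # (signatures, exposures, error, trace, warm)
    for r, rng in enumerate(streams):
        warm = r == 0 and _warm_start is not None
        if warm:
            W, H, trace = _mu_kl_nmf(V, k, rng, n_iter, tol, W0=_warm_start[0], H0=_warm_start[1])
        else:
            W, H, trace = _mu_kl_nmf(V, k, rng, n_iter, tol)
        Wn, Hn = _normalize(W, H)
        runs.append((Wn, Hn, float(trace[-1]), trace, warm))

    W, H, err, trace, _ = min(runs, key=lambda t: t[2])
    # stability is measured across the random initializations only: the warm
    # start (used by select_rank to keep the error curve non-increasing in k)
    # may sit in its own basin with a degenerate extra component
    random_sigs = [t[0] for t in runs if not t[4]]
    ref = min((t for t in runs if not t[4]), key=lambda t: t[2])[0] if random_sigs else W
    stability = _restart_stability(ref, random_sigs)
    return SignatureSet(
        signatures=W,
        exposures=H,
        recon_error=float(err),
        k=k,
        restart_stability=stability,
        objective_trace=trace,
    )


def match_signatures(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-cosine pairing of two signature matrices (columns).

    Returns (columns of B matched to columns of A, matched cosines); uses
    Hungarian assignment on the cosine matrix, ties broken by index.
    """
    k = A.shape[1]
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            C[i, j] = cosine_sim(A[:, i], B[:, j])
    rows, cols = optimize.linear_sum_assignment(-C)
    return cols, C[rows, cols]


def _restart_stability(ref: np.ndarray, restarts: list[np.ndarray]) -> float:
    """Worst matched cosine of any restart's signatures to the best restart's.

    A factorization is only as reproducible as its least reproducible
    component, so the summary is the minimum over components and restarts;
    the mean is far less discriminating because two arbitrary flat-ish
    spectra already have cosine near 0.9.
    """
    if len(restarts) <= 1:
        return 1.0
    cos = []
    for W in restarts:
        _, matched = match_signatures(ref, W)
        cos.extend(matched.tolist())
    return float(np.min(cos))


def select_rank(
    spectra: np.ndarray,
    k_range=range(1, 9),
    n_restarts: int = 10,
    seed: int = 0,
    stability_threshold: float = 0.9,
    min_error_improvement: float = 0.05,
    n_iter: int = 500,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of signatures from stability and error curves.

    For each k the spectra are factorized ``n_restarts`` times (one restart
    warm-started from the previous k's solution so the error curve is
    non-increasing in k); stability is the mean cosine of Hungarian-matched
    signatures across restarts. The chosen k is the largest whose stability
    exceeds the threshold and whose reconstruction error improves on k-1 by
    more than ``min_error_improvement`` (fractional); k=1 is the baseline.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ConfigError("empty k_range")
    rows = []
    prev_err = None
    prev_sol = None
    chosen = ks[0]
    for k in ks:
        warm = None
        if prev_sol is not None:
            W0 = np.column_stack([prev_sol[0], np.full((96, k - prev_sol[0].shape[1]), 1.0 / 96)])
            H0 = np.vstack(
                [prev_sol[1], np.full((k - prev_sol[1].shape[0], spectra.shape[1]), _EPS)]
            )
            warm = (W0[:, :k], H0[:k, :])
        fit = nmf_decompose(
            spectra, k, n_restarts=n_restarts, seed=seed, n_iter=n_iter, _warm_start=warm
        )
        improvement = np.nan if prev_err is None else (prev_err - fit.recon_error) / prev_err
        rows.append(
            {
                "k": k,
                "stability": fit.restart_stability,
                "recon_error": fit.recon_error,
                "error_improvement": improvement,
            }
        )
        ok_stab = fit.restart_stability > stability_threshold
        ok_err = prev_err is None or improvement > min_error_improvement
        if ok_stab and ok_err:
            chosen = k
        prev_err = fit.recon_error
        prev_sol = (fit.signatures, fit.exposures)
    return chosen, pd.DataFrame(rows)


def refit_exposures(spectra: np.ndarray, signatures: np.ndarray) -> np.ndarray:
    """Per-cell nonnegative least squares against fixed signatures.

    ``signatures`` must be column-stochastic; the returned k x n exposures
    are in mutation-count units.
    """
    V = np.atleast_2d(np.asarray(spectra, dtype=float))
    if V.shape[0] != signatures.shape[0]:
        if V.shape[1] == signatures.shape[0]:  # accept a single spectrum as a row
            V = V.T
        else:
            raise ConfigError(
                f"spectra ({V.shape}) and signatures ({signatures.shape}) do not align"
            )
    if not np.allclose(signatures.sum(axis=0), 1.0, atol=1e-6):
        raise ConfigError("signatures must be column-stochastic")
    k, n = signatures.shape[1], V.shape[1]
    E = np.zeros((k, n))
    for c in range(n):
        E[:, c], _ = optimize.nnls(signatures, V[:, c])
    return E


def attribute_exposures(
    spectra: np.ndarray,
    denovo_signatures: np.ndarray,
    references: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Quantify per-cell exposures, optionally against matched references.

    De novo factorization of spectra whose mixing proportions span only a
    narrow range recovers each component only up to the data hull, so the
    minor component comes out blended with the major one. The standard
    remedy is to use the de novo solution to fix the number and identity
    of the components and then quantify exposures against the matched
    *reference* vectors (the role COSMIC signatures play in practice).

    Returns ``(exposures, basis, path)`` where ``basis`` is the signature
    matrix actually used (reference columns reordered to match the de novo
    columns when references are given) and ``path`` records which route
    produced the exposures ("matched_reference" or "de_novo").
    """
    if references is not None and references.shape == denovo_signatures.shape:
        cols, _ = match_signatures(denovo_signatures, references)
        basis = references[:, cols]
        basis = basis / basis.sum(axis=0)
        return refit_exposures(spectra, basis), basis, "matched_reference"
    return refit_exposures(spectra, denovo_signatures), denovo_signatures, "de_novo"


def burden_age_regression(values, ages) -> RegressionFit:
    """OLS of a per-cell value on donor age with free intercept.

    Slope is in units of the value per year; the p-value is the two-sided
    test of zero slope.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise ConfigError("values and ages must be 1-D and aligned")
    if v.size < 3:
        raise DataError(f"need at least 3 points for a reported fit, got {v.size}")
    if np.ptp(a) == 0:
        raise DataError("constant ages: degenerate design")
    if np.allclose(v, 0):
        return RegressionFit(slope=0.0, intercept=0.0, r_squared=0.0, p_value=1.0, n=v.size)
    res = stats.linregress(a, v)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(v.size),
    )
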