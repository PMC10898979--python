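"""Fourier-based anechoic demixing (FADA).

Cyclic multichannel data are modelled as an *anechoic mixture*: each
channel (degree of freedom) in each cycle is a weighted sum of a small
number of shared periodic basis functions ("sources"), each circularly
shifted by a channel- and source-specific time delay::

    x_m(t) = sum_p  c_mp * s_p((t - tau_mp) mod P)  + mean_m + residual

Because the cycles are periodic with a fixed normalized length P, the
model becomes algebraic on the cycle-locked harmonic grid k = 1..K: the
Fourier coefficients of channel r satisfy

    c_rk = sum_u a_ru * exp(-2*pi*i*k*tau_ru/P) * v_uk

where v_uk are the source coefficients.  The fit proceeds by

1. a seeded multiplicative-update non-negative matrix factorization of the
   squared coefficient magnitudes ``|c_rk|^2 ~ sum_u |a_ru|^2 |v_uk|^2``
   (initialization of magnitudes; source phases start at zero),
2. per-channel exact least-squares updates of each (weight, delay) pair —
   the optimal delay maximizes an FFT-evaluated circular correlation and
   is refined by parabolic interpolation, so delays are continuous in
   ``[0, P)``,
3. a per-harmonic complex least-squares refit of the source coefficients
   with the weights and delays fixed,

iterated to convergence of the relative residual.  Sources are rebuilt
from conjugate-symmetric coefficients, hence real by construction, and
are renormalized to unit L2 after every outer iteration with the scale
pushed into the weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF
from sklearn.utils.validation import check_is_fitted, check_random_state

from .evaluation import _circular_correlation

__all__ = ["AnechoicDemixing", "SourceSet", "align_sources", "fit_fada", "reconstruct_signals"]


@dataclass
class SourceSet:
    """An anechoic decomposition of stacked cycles.

    ``sources`` is ``(n_src, P)`` with unit-L2 rows; ``weights`` and
    ``delays`` are ``(n_cycles, n_channels, n_src)`` (delays in samples,
    circular in ``[0, P)``); ``channel_means`` is ``(n_cycles,
    n_channels)``; ``residual_fraction`` is the per-channel fraction of
    (mean-removed) variance not captured by the reconstruction.
    """

    sources: np.ndarray
    weights: np.ndarray
    delays: np.ndarray
    channel_means: np.ndarray
    residual_fraction: np.ndarray
    channel_names: list[str] | None = None

    @property
    def n_src(self) -> int:
        return self.sources.shape[0]

    @property
    def P(self) -> int:
        return self.sources.shape[1]

    def to_dict(self) -> dict:
        return {
            "sources": self.sources.tolist(),
            "weights": self.weights.tolist(),
            "delays": self.delays.tolist(),
            "channel_means": self.channel_means.tolist(),
            "residual_fraction": self.residual_fraction.tolist(),
            "channel_names": self.channel_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceSet":
        return cls(
            np.asarray(d["sources"], dtype=float),
            np.asarray(d["weights"], dtype=float),
            np.asarray(d["delays"], dtype=float),
            np.asarray(d["channel_means"], dtype=float),
            np.asarray(d["residual_fraction"], dtype=float),
            d.get("channel_names"),
        )

    def save(self, path) -> None:
        """Write metadata/weights/delays as JSON plus the waveforms as TSV."""
        import json
        from pathlib import Path

        path = Path(path)
        meta = self.to_dict()
        del meta["sources"]
        path.write_text(json.dumps(meta, indent=1))
        waves = path.with_suffix(".sources.tsv")
        header = "\t".join(f"s{p + 1}" for p in range(self.n_src))
        np.savetxt(waves, self.sources.T, delimiter="\t", header=header, comments="")

    @classmethod
    def load(cls, path) -> "SourceSet":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.read_text())
        meta["sources"] = np.loadtxt(
            path.with_suffix(".sources.tsv"), delimiter="\t", skiprows=1
        ).T
        return cls.from_dict(meta)


# ---------------------------------------------------------------------------
# internal frequency-domain helpers


def _as_cycles(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3:
        raise ValueError("expected cycles of shape (n_cycles, n_channels, P) or (n_channels, P)")
    return X


def _source_waveforms(V: np.ndarray, P: int) -> np.ndarray:
    """Real time-domain sources from harmonic coefficients ``V`` (U, K)."""
    U, K = V.shape
    full = np.zeros((U, P // 2 + 1), dtype=complex)
    full[:, 1 : K + 1] = V
    return np.fft.irfft(full, n=P, axis=1)


def _delay_correlogram(H: np.ndarray, P: int, oversample: int = 8) -> np.ndarray:
    """Correlation-vs-delay curves ``g_r(tau)`` for rows of ``H``.

    ``H[r, k-1] = resid_rk * conj(v_uk)``; ``g_r(tau) = 2*Re sum_k H_rk
    e^{2 pi i k tau/P}`` evaluated on a grid of ``P * oversample`` delays
    (the factor 2 accounts for the conjugate-symmetric negative
    harmonics).
    """
    R, K = H.shape
    N = P * oversample
    # the conjugate-symmetric negative band makes g real: an inverse real
    # FFT computes 2*Re(sum_k H_k e^{2 pi i k m / N}) directly
    hpad = np.zeros((R, N // 2 + 1), dtype=complex)
    hpad[:, 1 : K + 1] = H
    return np.fft.irfft(hpad, n=N, axis=1) * N


def _best_delays(
    H: np.ndarray,
    v_power: float,
    P: int,
    oversample: int = 8,
    window: tuple[np.ndarray, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row optimal (weight, delay) for one source against residual rows.

    The least-squares objective for a single (weight, delay) pair reduces
    to maximizing ``|g_r(tau)|``; the grid maximum is refined by parabolic
    interpolation, so delays are continuous in ``[0, P)``.  Signed weights
    follow as ``g_r(tau*) / v_power``.  With ``window = (centres,
    halfwidth)`` the search is confined to a circular delay window per
    row (used to keep per-cycle delays anchored to the channel-level
    consensus).
    """
    g = _delay_correlogram(H, P, oversample)
    N = g.shape[1]
    absg = np.abs(g)
    if window is not None:
        centres, halfwidth = window
        grid = np.arange(N) / oversample
        dist = np.abs((grid[None, :] - np.asarray(centres)[:, None] + P / 2) % P - P / 2)
        absg = np.where(dist <= halfwidth, absg, -np.inf)
    m = np.argmax(absg, axis=1)
    rows = np.arange(len(m))
    gm = np.abs(g[rows, (m - 1) % N])
    g0 = np.abs(g[rows, m])
    gp = np.abs(g[rows, (m + 1) % N])
    denom = gm - 2 * g0 + gp
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom != 0, 0.5 * (gm - gp) / denom, 0.0)
    frac = np.clip(frac, -0.5, 0.5)
    tau = np.mod((m + frac) / oversample, P)
    k = np.arange(1, H.shape[1] + 1)
    g_opt = 2.0 * np.real(np.sum(H * np.exp(2j * np.pi * k[None, :] * tau[:, None] / P), axis=1))
    a = g_opt / v_power if v_power > 0 else np.zeros_like(g_opt)
    return a, tau


def _fit_weight_delay(h: np.ndarray, v_power: float, P: int, oversample: int = 8
                      ) -> tuple[float, float, float]:
    """Single-row version of :func:`_best_delays` (kept for clarity/tests)."""
    a, tau = _best_delays(h[None, :], v_power, P, oversample)
    k = np.arange(1, len(h) + 1)
    g_opt = 2.0 * float(np.real(np.sum(h * np.exp(2j * np.pi * k * tau[0] / P))))
    return float(a[0]), float(tau[0]), g_opt


def _model_coeffs(A: np.ndarray, T: np.ndarray, V: np.ndarray, P: int) -> np.ndarray:
    """Model coefficients ``Z_rk = sum_u a_ru e^{-2 pi i k tau_ru / P} v_uk``."""
    K = V.shape[1]
    k = np.arange(1, K + 1)
    ramp = np.exp(-2j * np.pi * T[:, :, None] * k[None, None, :] / P)
    return np.einsum("ru,ruk,uk->rk", A, ramp, V)


class AnechoicDemixing(TransformerMixin, BaseEstimator):
    """Anechoic blind source separation of cycle-normalized trajectories.

    Parameters
    ----------
    n_sources : int, default 3
        Number of temporal basis functions to extract.
    n_harmonics : int, default 10
        Cycle-locked harmonics retained (band-limited signal model).
    max_iter : int, default 500
        Maximum outer iterations.
    tol : float, default 1e-8
        Convergence threshold on the relative change of the total squared
        residual.
    delay_mode : {"cycle", "trial"}, default "cycle"
        Whether each cycle gets its own weights/delays or one set is
        shared by all cycles of a channel.
    n_sweeps : int, default 2
        Coordinate-descent sweeps over sources per outer iteration.
    random_state : int, RandomState or None
        Seed for the non-negative initialization.

    Attributes
    ----------
    sources_ : ndarray (n_sources, P)
        Unit-L2 real source waveforms.
    source_coeffs_ : ndarray (n_sources, n_harmonics), complex
        Their positive-frequency Fourier coefficients.
    weights_, delays_ : ndarray (n_cycles, n_channels, n_sources)
    channel_means_ : ndarray (n_cycles, n_channels)
    residual_fraction_ : ndarray (n_channels,)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_sources: int = 3,
        n_harmonics: int = 10,
        max_iter: int = 500,
        tol: float = 1e-8,
        delay_mode: str = "cycle",
        n_sweeps: int = 2,
        n_restarts: int = 3,
        alias_correction: bool = True,
        random_state: int | None = None,
    ):
        self.n_sources = n_sources
        self.n_harmonics = n_harmonics
        self.max_iter = max_iter
        self.tol = tol
        self.delay_mode = delay_mode
        self.n_sweeps = n_sweeps
        self.n_restarts = n_restarts
        self.alias_correction = alias_correction
        self.random_state = random_state

    def _refit_sources(self, C, A, T, V, P) -> None:
        """Per-harmonic complex least-squares source update, in place."""
        K = V.shape[1]
        k = np.arange(1, K + 1)
        ramp = np.exp(-2j * np.pi * T[:, :, None] * k[None, None, :] / P)
        for ki in range(K):
            V[:, ki], *_ = np.linalg.lstsq(A * ramp[:, :, ki], C[:, ki], rcond=None)

    def _alias_sweep(
        self, C: np.ndarray, A: np.ndarray, T: np.ndarray, V: np.ndarray,
        P: int, shape: tuple[int, int], halfwidth: float = 6.0,
    ) -> None:
        """Channel-consensus alias correction of per-cycle delays, in place.

        A source whose waveform partially reproduces itself under a
        circular shift (autocorrelation sidelobe) offers alias delays that
        fit one noisy cycle almost as well as the true delay, with the
        other sources' per-cycle freedom absorbing the difference.  The
        cycles of a channel share one generative delay up to small
        jitter, so the basins are re-decided jointly where discrimination
        is strongest: a beam search over correlogram-peak delay
        combinations with weights and delays *tied across cycles*, after
        which the per-cycle fits are re-freed within ``halfwidth``
        samples of the tied consensus.
        """
        for _ in range(2):
            self._beam_rows(C, A, T, V, P, shape, beam_width=8, tie=True)
            for _ in range(2):
                self._update_rows(C, A, T, V, P, shape, tie=True, oversample=8)
            self._refit_sources(C, A, T, V, P)
        anchors = T.copy()
        for _ in range(4):
            self._update_rows(
                C, A, T, V, P, shape, tie=False, window=(anchors, halfwidth), oversample=8
            )
            self._refit_sources(C, A, T, V, P)

    def _alternate(
        self,
        C: np.ndarray,
        A: np.ndarray,
        T: np.ndarray,
        V: np.ndarray,
        P: int,
        shape: tuple[int, int],
        total_power: float,
        use_beam: bool = True,
        tie: bool | None = None,
        n_iter: int | None = None,
    ) -> tuple[float, int, bool]:
        """Run the alternating refinement in place; returns (residual, iters, converged)."""
        prev = np.inf
        converged = False
        it = 0
        history: list[float] = []
        for it in range(n_iter if n_iter is not None else self.max_iter):
            if use_beam and it < 21 and it % 5 == 0:
                self._beam_rows(C, A, T, V, P, shape, tie=tie)
            self._update_rows(C, A, T, V, P, shape, tie=tie)
            self._refit_sources(C, A, T, V, P)
            resid = float(np.sum(np.abs(C - _model_coeffs(A, T, V, P)) ** 2))
            history.append(resid)
            if prev < np.inf and abs(prev - resid) <= self.tol * max(
                resid, 1e-12 * total_power
            ):
                converged = True
                break
            prev = resid
        self.residual_history_ = np.asarray(history)
        return resid, it + 1, converged

    # -- core alternating solver -------------------------------------------

    def _update_rows(
        self, C: np.ndarray, A: np.ndarray, T: np.ndarray, V: np.ndarray,
        P: int, shape: tuple[int, int],
        tie: bool | None = None,
        window: tuple[np.ndarray, float] | None = None,
        oversample: int = 4,
    ) -> None:
        """Exact coordinate (weight, delay) updates for all rows, in place.

        With ``tie`` (default: delay_mode == "trial") the fit is tied
        across the cycles of a channel by summing the delay correlograms
        over the tie group; otherwise every (cycle, channel) row gets its
        own pair.  ``window = (centres (R, U), halfwidth)`` confines each
        delay to a circular window.
        """
        L, M = shape
        U = self.n_sources
        K = V.shape[1]
        k = np.arange(1, K + 1)
        if tie is None:
            tie = self.delay_mode == "trial"
        v_power = 2.0 * np.sum(np.abs(V) ** 2, axis=1)  # conj-symmetric pairs
        resid = C - _model_coeffs(A, T, V, P)
        for _ in range(self.n_sweeps):
            for u in range(U):
                contrib = (
                    A[:, u, None]
                    * np.exp(-2j * np.pi * T[:, u, None] * k[None, :] / P)
                    * V[u][None, :]
                )
                resid_u = resid + contrib
                H = resid_u * np.conj(V[u])[None, :]
                win_u = None if window is None else (window[0][:, u], window[1])
                if tie:
                    Hg = H.reshape(L, M, K).sum(axis=0)
                    win_g = None if win_u is None else (win_u[0][:M], win_u[1])
                    a, tau = _best_delays(Hg, L * v_power[u], P, oversample, window=win_g)
                    a = np.tile(a, L)
                    tau = np.tile(tau, L)
                else:
                    a, tau = _best_delays(H, v_power[u], P, oversample, window=win_u)
                A[:, u] = a
                T[:, u] = tau
                resid = resid_u - (
                    a[:, None] * np.exp(-2j * np.pi * tau[:, None] * k[None, :] / P) * V[u][None, :]
                )

    def _beam_rows(
        self, C: np.ndarray, A: np.ndarray, T: np.ndarray, V: np.ndarray,
        P: int, shape: tuple[int, int], beam_width: int = 6, oversample: int = 4,
        tie: bool | None = None,
    ) -> None:
        """Joint per-row delay search over a beam of correlogram peaks.

        Coordinate updates cannot move two delays at once, which traps
        rows in joint-delay local minima; this step enumerates all
        combinations of the top ``beam_width`` correlation peaks per
        source and solves the exact (real) weight least squares for each,
        keeping the best.  Used during the early iterations only.
        """
        L, M = shape
        U, K = V.shape
        k = np.arange(1, K + 1)
        if tie is None:
            tie = self.delay_mode == "trial"
        if tie:
            groups = [np.arange(m, L * M, M) for m in range(M)]
        else:
            groups = [np.array([r]) for r in range(C.shape[0])]
        # candidate peaks come from the residual after removing the other
        # sources' current contributions — raw-channel correlograms of a weak
        # source are masked by the strong ones
        resid = C - _model_coeffs(A, T, V, P)
        g_all = []
        for u in range(U):
            contrib = (
                A[:, u, None]
                * np.exp(-2j * np.pi * T[:, u, None] * k[None, :] / P)
                * V[u][None, :]
            )
            g_all.append(
                _delay_correlogram((resid + contrib) * np.conj(V[u])[None, :], P, oversample)
            )
        for rows in groups:
            cand_cols = []
            cand_taus = []
            for u in range(U):
                g = np.abs(g_all[u][rows].sum(axis=0))
                # local maxima on the circular grid
                peaks = np.flatnonzero((g > np.roll(g, 1)) & (g >= np.roll(g, -1)))
                if len(peaks) == 0:
                    peaks = np.array([int(np.argmax(g))])
                peaks = peaks[np.argsort(-g[peaks])][:beam_width]
                taus = peaks / oversample
                cand_taus.append(taus)
                cand_cols.append(
                    np.exp(-2j * np.pi * taus[:, None] * k[None, :] / P) * V[u][None, :]
                )
            # batched real-weight least squares over all delay combinations:
            # the doubled real part accounts for the conjugate negative band
            n_rows = len(rows)
            csum = C[rows].sum(axis=0)
            c2 = float(np.sum(np.abs(C[rows]) ** 2)) * 2.0
            gram = [
                [2.0 * n_rows * np.real(cand_cols[i] @ cand_cols[j].conj().T) for j in range(U)]
                for i in range(U)
            ]
            rhs = [2.0 * np.real(cand_cols[i].conj() @ csum) for i in range(U)]
            combos = np.stack(
                np.meshgrid(*[np.arange(len(t)) for t in cand_taus], indexing="ij"), axis=-1
            ).reshape(-1, U)
            nc = combos.shape[0]
            G = np.empty((nc, U, U))
            b = np.empty((nc, U))
            for i in range(U):
                b[:, i] = rhs[i][combos[:, i]]
                for j in range(U):
                    G[:, i, j] = gram[i][j][combos[:, i], combos[:, j]]
            G += 1e-9 * np.trace(G, axis1=1, axis2=2)[:, None, None] * np.eye(U)[None]
            try:
                a_all = np.linalg.solve(G, b[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate candidates
                continue
            resid_all = c2 - np.einsum("ni,ni->n", a_all, b)
            n_best = int(np.argmin(resid_all))
            old = 2.0 * float(
                np.sum(np.abs(C[rows] - _model_coeffs(A[rows], T[rows], V, P)) ** 2)
            )
            if resid_all[n_best] < old:
                A[rows] = a_all[n_best]
                T[rows] = np.array(
                    [cand_taus[u][combos[n_best, u]] for u in range(U)]
                )

    def fit(self, X: np.ndarray, y: None = None) -> "AnechoicDemixing":
        """Fit the decomposition to stacked cycles.

        ``X`` has shape ``(n_cycles, n_channels, P)`` (a single cycle set
        ``(n_channels, P)`` is also accepted).
        """
        X = _as_cycles(X)
        L, M, P = X.shape
        U, K = self.n_sources, self.n_harmonics
        if K > P // 2:
            raise ValueError("n_harmonics must be at most P/2")
        if U > M:
            raise ValueError("n_sources cannot exceed the number of channels")
        if self.delay_mode not in ("cycle", "trial"):
            raise ValueError("delay_mode must be 'cycle' or 'trial'")
        rng = check_random_state(self.random_state)

        means = X.mean(axis=2)
        C = np.fft.rfft(X - means[:, :, None], axis=2)[:, :, 1 : K + 1]
        C = C.reshape(L * M, K)  # rows are (cycle, channel) pairs, cycle-major
        R = L * M
        mag2 = np.abs(C) ** 2
        if U > min(R, K) or np.linalg.matrix_rank(mag2) < U:
            raise ValueError("n_sources exceeds the rank of the magnitude matrix")
        total_power = float(np.sum(mag2))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nmf = NMF(
                n_components=U, init="random", solver="mu", max_iter=800,
                random_state=rng, tol=1e-6,
            )
            W0 = nmf.fit_transform(mag2)
        H0 = nmf.components_

        best: tuple = (np.inf, None)
        history: list[float] = []
        explore_iter = min(120, self.max_iter)
        for restart in range(max(1, self.n_restarts)):
            A = np.sqrt(W0)
            phases = (
                np.zeros((U, K))
                if restart == 0
                else rng.uniform(0, 2 * np.pi, (U, K))
            )
            V = np.sqrt(H0).astype(complex) * np.exp(1j * phases)
            T = np.zeros((R, U))
            resid, n_it, converged = self._alternate(
                C, A, T, V, P, (L, M), total_power, use_beam=True, n_iter=explore_iter
            )
            history.append(resid)
            if resid < best[0]:
                best = (resid, (A, T, V), n_it, converged)
            if resid <= 1e-10 * total_power:
                break
        resid, (A, T, V), n_it, converged = best
        if not converged and self.max_iter > explore_iter:
            # continue only the best exploratory run to full convergence
            resid, n_more, converged = self._alternate(
                C, A, T, V, P, (L, M), total_power, use_beam=False,
                n_iter=self.max_iter - explore_iter,
            )
            n_it += n_more
        self.converged_ = converged
        if not self.converged_:
            warnings.warn(
                f"anechoic demixing did not converge in {self.max_iter} iterations; "
                "returning the best iterate",
                RuntimeWarning,
            )
        self.n_iter_ = n_it
        self.restart_residuals_ = np.asarray(history)

        if self.delay_mode == "cycle" and L > 1 and self.alias_correction:
            self._alias_sweep(C, A, T, V, P, (L, M))

        # unit-L2 gauge: push source scale into the weights
        s = _source_waveforms(V, P)
        norms = np.linalg.norm(s, axis=1)
        norms[norms == 0] = 1.0
        V = V / norms[:, None]
        A = A * norms[None, :]

        self.n_features_in_ = M
        self.P_ = P
        self.source_coeffs_ = V
        self.sources_ = _source_waveforms(V, P)
        self.weights_ = A.reshape(L, M, U)
        self.delays_ = T.reshape(L, M, U)
        self.channel_means_ = means
        rec = self.inverse_transform(self.weights_, self.delays_, self.channel_means_)
        num = np.sum((X - rec) ** 2, axis=(0, 2))
        den = np.sum((X - means[:, :, None]) ** 2, axis=(0, 2))
        den[den == 0] = 1.0
        self.residual_fraction_ = num / den
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new cycles on the fitted sources.

        Estimates per-cycle weights and delays with the sources fixed and
        returns the weights, shape ``(n_cycles, n_channels, n_sources)``
        (see ``encode`` for the delays as well).
        """
        return self.encode(X)[0]

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Weights, delays and channel means for new cycles, sources fixed."""
        check_is_fitted(self, "sources_")
        X = _as_cycles(X)
        L, M, P = X.shape
        if P != self.P_:
            raise ValueError("cycle length differs from the fitted P")
        K, U = self.n_harmonics, self.n_sources
        means = X.mean(axis=2)
        C = np.fft.rfft(X - means[:, :, None], axis=2)[:, :, 1 : K + 1].reshape(L * M, K)
        A = np.zeros((L * M, U))
        T = np.zeros((L * M, U))
        V = self.source_coeffs_.copy()
        self._beam_rows(C, A, T, V, P, (L, M))
        for _ in range(4):
            self._update_rows(C, A, T, V, P, (L, M))
        return A.reshape(L, M, U), T.reshape(L, M, U), means

    def inverse_transform(
        self, weights: np.ndarray, delays: np.ndarray, channel_means: np.ndarray | None = None
    ) -> np.ndarray:
        """Reconstruct cycles from weights/delays under the fitted sources."""
        check_is_fitted(self, "sources_")
        L, M, U = weights.shape
        K = self.n_harmonics
        k = np.arange(1, K + 1)
        ramp = np.exp(
            -2j * np.pi * delays.reshape(L * M, U)[:, :, None] * k[None, None, :] / self.P_
        )
        Z = np.einsum("ru,ruk,uk->rk", weights.reshape(L * M, U), ramp, self.source_coeffs_)
        full = np.zeros((L * M, self.P_ // 2 + 1), dtype=complex)
        full[:, 1 : K + 1] = Z
        rec = np.fft.irfft(full, n=self.P_, axis=1).reshape(L, M, self.P_)
        if channel_means is not None:
            rec = rec + np.asarray(channel_means)[:, :, None]
        return rec

    def to_source_set(self, channel_names: list[str] | None = None) -> SourceSet:
        check_is_fitted(self, "sources_")
        return SourceSet(
            sources=self.sources_.copy(),
            weights=self.weights_.copy(),
            delays=self.delays_.copy(),
            channel_means=self.channel_means_.copy(),
            residual_fraction=self.residual_fraction_.copy(),
            channel_names=channel_names,
        )


def fit_fada(
    cycles: np.ndarray,
    n_src: int = 3,
    K: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
    delay_mode: str = "cycle",
) -> SourceSet:
    """Convenience wrapper: fit :class:`AnechoicDemixing` and return a SourceSet."""
    est = AnechoicDemixing(
        n_sources=n_src, n_harmonics=K, max_iter=max_iter, tol=tol,
        delay_mode=delay_mode, random_state=seed,
    ).fit(cycles)
    return est.to_source_set()


def reconstruct_signals(ss: SourceSet, n_harmonics: int | None = None) -> np.ndarray:
    """Reconstruct per-channel cycles from a SourceSet.

    ``x_m = sum_p c_mp * shift(s_p, tau_mp) + mean_m``, with fractional
    delays applied through Fourier phase ramps.
    """
    L, M, U = ss.weights.shape
    P = ss.P
    Sf = np.fft.rfft(ss.sources, axis=1)
    k = np.arange(Sf.shape[1])
    ramp = np.exp(-2j * np.pi * ss.delays[..., None] * k / P)  # (L, M, U, K)
    Xf = np.einsum("lmu,lmuk,uk->lmk", ss.weights, ramp, Sf)
    rec = np.fft.irfft(Xf, n=P, axis=2)
    return rec + ss.channel_means[:, :, None]


def align_sources(ss: SourceSet, ref: SourceSet | np.ndarray) -> SourceSet:
    """Resolve the permutation/sign/shift ambiguity against a reference.

    Finds the one-to-one assignment maximizing total absolute circular
    cross-correlation with the reference sources, then permutes, circularly
    shifts and sign-flips the sources — compensating the weights and delays
    so the reconstruction is unchanged to machine precision.
    """
    from itertools import permutations

    R = ref.sources if isinstance(ref, SourceSet) else np.asarray(ref, dtype=float)
    n, P = ss.sources.shape
    if R.shape != (n, P):
        raise ValueError("reference must have the same n_src and P")
    score = np.empty((n, n))
    lags = np.empty((n, n), dtype=int)
    signs = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            r = _circular_correlation(R[j], ss.sources[i])
            lag = int(np.argmax(np.abs(r)))
            score[i, j] = abs(r[lag])
            lags[i, j] = lag
            signs[i, j] = np.sign(r[lag]) or 1.0
    perm = max(permutations(range(n)), key=lambda p: sum(score[i, p[i]] for i in range(n)))
    # source i becomes output slot perm[i]
    new_sources = np.empty_like(ss.sources)
    new_weights = np.empty_like(ss.weights)
    new_delays = np.empty_like(ss.delays)
    for i in range(n):
        j = perm[i]
        lag, sg = lags[i, j], signs[i, j]
        # ref_j(t) ~ sg * s_i(t + lag)  =>  aligned source s'_j(t) = sg * s_i(t + lag)
        new_sources[j] = sg * np.roll(ss.sources[i], -lag)
        # c * s_i(t - tau) = (c*sg) * s'_j(t - (tau + lag))
        new_weights[..., j] = sg * ss.weights[..., i]
        new_delays[..., j] = np.mod(ss.delays[..., i] + lag, P)
    return replace(ss, sources=new_sources, weights=new_weights, delays=new_delays)
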