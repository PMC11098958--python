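"""TCSPC lifetime fitting, FRET efficiencies, and Hill titration analysis.

Photon-count decay histograms (default 16 ps binning) are tail-fit from
the peak bin with a sum of exponentials Σ a_k·exp(−t/τ_k) under Poisson
weighting; the amplitude-weighted mean lifetime τ_amp = Σ a_k τ_k / Σ a_k
of a donor+acceptor sample, together with the donor-only lifetime τ_D
(3.52 ns for the reference donor), gives the FRET efficiency

    E = 100 · (1 − τ_DA / τ_D)   [percent].

FRET-versus-[Ca²⁺] titrations are described by the Hill function

    y = START + (END − START) · xⁿ / (Kⁿ + xⁿ),

fit globally across experimental conditions with a single shared Hill
coefficient n and independent START/END/K per condition; K is optimized on
a log10 scale with multi-start selection.  Binding constants across
conditions are compared by one-way ANOVA with Šidák-adjusted pairwise
t tests.

No instrument-response deconvolution is performed: with lifetimes in the
ns range and 16 ps bins, tail fitting from the peak is adequate.
Concentrations are molar throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "DecayHistogram",
    "LifetimeFit",
    "FretPairMetadata",
    "HillParams",
    "GlobalFitResult",
    "KcaComparison",
    "DecayModel",
    "fit_decay",
    "amplitude_weighted_lifetime",
    "fret_efficiency",
    "hill_curve",
    "GlobalHillModel",
    "fit_hill_global",
    "normalize_curve",
    "compare_kca",
]

TAU_D_DEFAULT = 3.52  # ns, donor-only single-exponential lifetime


@dataclass
class DecayHistogram:
    """Photon arrival histogram: integer counts per time bin."""

    counts: np.ndarray
    bin_width_ps: float = 16.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_width_ps <= 0:
            raise ValueError("bin width must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def times_ns(self) -> np.ndarray:
        """Bin-center times in ns."""
        return (np.arange(len(self.counts)) + 0.5) * self.bin_width_ps * 1e-3

    @property
    def window_ns(self) -> float:
        return len(self.counts) * self.bin_width_ps * 1e-3

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([np.arange(len(self.counts)) * self.bin_width_ps, self.counts]),
            fmt="%.1f %d",
            header="time_ps counts",
        )

    @classmethod
    def from_text(cls, path) -> "DecayHistogram":
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("expected two columns: time (ps), counts")
        t, c = data[:, 0], data[:, 1]
        widths = np.diff(t)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("time bins must be uniform")
        return cls(counts=c.astype(int), bin_width_ps=float(widths[0]) if len(widths) else 16.0)


@dataclass(frozen=True)
class FretPairMetadata:
    """Donor/acceptor pair constants (metadata only; no distance inversion)."""

    forster_distance_angstrom: float = 63.34
    tau_d_ns: float = TAU_D_DEFAULT

    def __post_init__(self) -> None:
        if self.forster_distance_angstrom <= 0 or self.tau_d_ns <= 0:
            raise ValueError("R0 and τ_D must be positive")


@dataclass
class LifetimeFit:
    components: list[tuple[float, float]]  # (amplitude, τ ns), descending τ
    tau_amp: float                         # ns
    chisq_reduced: float
    fit_start_bin: int
    at_bounds: bool = False

    @property
    def lifetimes(self) -> list[float]:
        return [tau for _, tau in self.components]


def amplitude_weighted_lifetime(components: Sequence[tuple[float, float]]) -> float:
    """τ_amp = Σ a_k τ_k / Σ a_k (ns)."""
    a = np.array([c[0] for c in components], dtype=float)
    tau = np.array([c[1] for c in components], dtype=float)
    if np.any(a < 0):
        raise ValueError("amplitudes must be non-negative")
    if a.sum() <= 0:
        raise ValueError("at least one amplitude must be positive")
    return float(np.sum(a * tau) / a.sum())


class DecayModel(BaseEstimator):
    """Tail-fit a decay histogram with 1 or 2 exponential components.

    fit(histogram) exposes ``components_`` ((amplitude, τ ns), descending
    τ), ``tau_amp_``, and ``result_`` (:class:`LifetimeFit`).  Fitting
    maximizes the Poisson likelihood of the per-bin counts (least squares
    on signed deviance residuals), starting at the histogram peak bin (or
    an explicit bin).  Weighting by observed counts instead of the model
    systematically underestimates the lifetimes of low-count tails, so the
    exact Poisson deviance is used.
    """

    def __init__(self, n_components: int = 2, fit_start: "int | str" = "peak_bin"):
        self.n_components = n_components
        self.fit_start = fit_start

    def fit(self, X: DecayHistogram, y=None) -> "DecayModel":
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        counts = np.asarray(X.counts, dtype=float)
        if counts.sum() < 1_000:
            raise ValueError(f"too few photons ({int(counts.sum())} < 1000)")
        start = int(np.argmax(counts)) if self.fit_start == "peak_bin" else int(self.fit_start)
        tail = counts[start:]
        if len(tail) < 50:
            raise ValueError(f"only {len(tail)} bins after fit start; need ≥ 50")
        t = (np.arange(len(tail)) + 0.5) * X.bin_width_ps * 1e-3  # ns from fit start

        # crude τ estimate from the 1/e point of the smoothed tail
        total = tail.sum()
        cum = np.cumsum(tail) / total
        tau0 = max(t[np.searchsorted(cum, 0.632)], t[1]) if total > 0 else 1.0
        a0 = tail[0] if tail[0] > 0 else total / len(tail)

        if self.n_components == 1:
            p0 = np.array([a0, tau0])
        else:
            p0 = np.array([0.6 * a0, 1.5 * tau0, 0.4 * a0, 0.5 * tau0])
        lo = np.tile([0.0, 1e-4], self.n_components)
        hi = np.tile([np.inf, 10.0 * X.window_ns], self.n_components)

        def resid(p):
            """Signed Poisson deviance residuals (zero-count bins contribute m)."""
            model = np.zeros_like(t)
            for k in range(self.n_components):
                model = model + p[2 * k] * np.exp(-t / p[2 * k + 1])
            m = np.maximum(model, 1e-12)
            term = np.where(
                tail > 0,
                m - tail + tail * np.log(np.maximum(tail, 1e-12) / m),
                m,
            )
            return np.sign(tail - m) * np.sqrt(2.0 * np.maximum(term, 0.0))

        sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf")
        if not sol.success:
            raise RuntimeError(f"decay fit did not converge: {sol.message}")
        comps = sorted(
            [(float(sol.x[2 * k]), float(sol.x[2 * k + 1])) for k in range(self.n_components)],
            key=lambda c: -c[1],
        )
        at_bounds = bool(np.any(np.isclose(sol.x, lo, atol=1e-12) & (lo > 0))
                         or np.any(np.isclose(sol.x, hi)))
        dof = max(len(tail) - len(sol.x), 1)
        self.components_ = comps
        self.tau_amp_ = amplitude_weighted_lifetime(comps)
        self.result_ = LifetimeFit(
            components=comps,
            tau_amp=self.tau_amp_,
            chisq_reduced=float(2.0 * sol.cost / dof),
            fit_start_bin=start,
            at_bounds=at_bounds,
        )
        return self


def fit_decay(
    histogram: DecayHistogram,
    n_components: int = 2,
    fit_start: "int | str" = "peak_bin",
) -> LifetimeFit:
    """Functional form of :class:`DecayModel`."""
    return DecayModel(n_components=n_components, fit_start=fit_start).fit(histogram).result_


def fret_efficiency(tau_da: float, tau_d: float = TAU_D_DEFAULT) -> float:
    """FRET efficiency in percent: E = 100·(1 − τ_DA/τ_D).

    τ_DA > τ_D yields a (physically suspect but reported-as-is) negative
    efficiency; a non-positive τ_D is an error.
    """
    if tau_d <= 0:
        raise ValueError("τ_D must be positive")
    if tau_da <= 0:
        raise ValueError("τ_DA must be positive")
    return 100.0 * (1.0 - tau_da / tau_d)


# -- Hill titration -----------------------------------------------------------

@dataclass
class HillParams:
    """Hill-function parameters: y = START + (END−START)·xⁿ/(Kⁿ + xⁿ)."""

    start: float  # FRET % at zero ligand
    end: float    # FRET % at saturation
    n: float      # Hill coefficient
    K: float      # binding constant, molar

    def __post_init__(self) -> None:
        if self.K <= 0 or self.n <= 0:
            raise ValueError("K and n must be positive")


def hill_curve(params: HillParams, x) -> np.ndarray:
    """Evaluate the Hill function at ligand concentration(s) x (molar)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    xn = np.power(x, params.n)
    out = params.start + (params.end - params.start) * xn / (params.K**params.n + xn)
    return out if out.ndim else float(out)


def normalize_curve(fit: HillParams, y) -> np.ndarray:
    """Map FRET % onto the 0–1 span of a fitted curve: (y − START)/(END − START)."""
    if fit.end == fit.start:
        raise ValueError("END = START: normalization undefined")
    y = np.asarray(y, dtype=float)
    out = (y - fit.start) / (fit.end - fit.start)
    return out if out.ndim else float(out)


@dataclass
class GlobalFitResult:
    n: float
    n_stderr: float
    conditions: dict  # condition -> {"start","end","K","start_stderr","end_stderr","K_stderr"}
    residuals: dict   # condition -> np.ndarray
    loss: float       # sum of squared residuals
    at_bounds: bool = False

    def params(self, condition) -> HillParams:
        c = self.conditions[condition]
        return HillParams(start=c["start"], end=c["end"], n=self.n, K=c["K"])


_N_BOUNDS = (0.3, 5.0)
_LOGK_BOUNDS = (-9.0, -3.0)  # K ∈ [1 nM, 1 mM]


class GlobalHillModel(BaseEstimator):
    """Global Hill fit: one shared Hill coefficient, per-condition START/END/K.

    Fit input is a tidy table with columns ``condition``, ``x`` (molar) and
    ``y`` (FRET %).  K is parameterized as log10(K/M) with bounds
    [1 nM, 1 mM]; n is bounded to [0.3, 5].  Five deterministic multi-starts
    (seeded from *seed*) are run and the lowest-loss solution kept; standard
    errors come from the Jacobian curvature at the optimum.  Fitting a
    single-condition table is the ordinary free fit.
    """

    def __init__(self, n_starts: int = 5, seed: int = 0):
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None, extra_starts: Optional[list[dict]] = None):
        df = X.rename(columns={"ca_free_molar": "x", "fret_percent": "y"})
        required = {"condition", "x", "y"}
        if not required.issubset(df.columns):
            raise ValueError(f"table needs columns {sorted(required)}")
        conditions = list(dict.fromkeys(df["condition"]))
        data = {
            c: (
                df.loc[df["condition"] == c, "x"].to_numpy(dtype=float),
                df.loc[df["condition"] == c, "y"].to_numpy(dtype=float),
            )
            for c in conditions
        }
        for c, (x, yv) in data.items():
            if len(np.unique(x)) < 5:
                raise ValueError(f"condition {c!r} has fewer than 5 distinct concentrations")

        # parameter vector: [n, (start, end, log10K) per condition]
        def unpack(p):
            n = p[0]
            per = {
                c: (p[1 + 3 * k], p[2 + 3 * k], 10.0 ** p[3 + 3 * k])
                for k, c in enumerate(conditions)
            }
            return n, per

        def resid(p):
            n, per = unpack(p)
            parts = []
            for c in conditions:
                x, yv = data[c]
                s, e, K = per[c]
                xn = np.power(x, n)
                parts.append(s + (e - s) * xn / (K**n + xn) - yv)
            return np.concatenate(parts)

        lo = [_N_BOUNDS[0]] + [-np.inf, -np.inf, _LOGK_BOUNDS[0]] * len(conditions)
        hi = [_N_BOUNDS[1]] + [np.inf, np.inf, _LOGK_BOUNDS[1]] * len(conditions)

        starts = []
        for i in range(self.n_starts):
            rng = np.random.default_rng(self.seed + i)
            p0 = [1.0 if i == 0 else float(rng.uniform(0.5, 3.0))]
            for c in conditions:
                x, yv = data[c]
                logk0 = (
                    float(np.log10(np.median(x)))
                    if i == 0
                    else float(rng.uniform(np.log10(x.min()), np.log10(x.max())))
                )
                p0 += [float(yv.min()), float(yv.max()), np.clip(logk0, *_LOGK_BOUNDS)]
            starts.append(np.array(p0))
        for d in extra_starts or []:
            p0 = [d["n"]]
            for c in conditions:
                p0 += [d[c]["start"], d[c]["end"], np.log10(d[c]["K"])]
            starts.append(np.clip(np.array(p0), lo, hi))

        best = None
        for p0 in starts:
            try:
                sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError("global Hill fit: no start converged")

        n, per = unpack(best.x)
        ss = float(2.0 * best.cost)  # sum of squared residuals
        dof = max(len(resid(best.x)) - len(best.x), 1)
        J = best.jac
        cov = np.linalg.pinv(J.T @ J) * (ss / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        cond_out, residuals = {}, {}
        offset = 0
        for k, c in enumerate(conditions):
            s, e, K = per[c]
            logk_se = se[3 + 3 * k]
            cond_out[c] = {
                "start": float(s),
                "end": float(e),
                "K": float(K),
                "start_stderr": float(se[1 + 3 * k]),
                "end_stderr": float(se[2 + 3 * k]),
                # delta method: SE(K) = ln(10)·K·SE(log10 K)
                "K_stderr": float(np.log(10.0) * K * logk_se),
            }
            x, yv = data[c]
            residuals[c] = hill_curve(HillParams(s, e, n, K), x) - yv
        at_bounds = bool(
            np.isclose(n, _N_BOUNDS).any()
            or any(
                np.isclose(np.log10(per[c][2]), _LOGK_BOUNDS, atol=1e-9).any()
                for c in conditions
            )
        )
        self.result_ = GlobalFitResult(
            n=float(n),
            n_stderr=float(se[0]),
            conditions=cond_out,
            residuals=residuals,
            loss=ss,
            at_bounds=at_bounds,
        )
        self.n_ = float(n)
        self.conditions_ = cond_out
        return self

    def predict(self, x, condition=None) -> np.ndarray:
        if condition is None:
            condition = next(iter(self.conditions_))
        return hill_curve(self.result_.params(condition), x)


def fit_hill_global(
    datasets: pd.DataFrame,
    n_starts: int = 5,
    seed: int = 0,
    extra_starts: Optional[list[dict]] = None,
) -> GlobalFitResult:
    """Functional form of :class:`GlobalHillModel`."""
    model = GlobalHillModel(n_starts=n_starts, seed=seed)
    model.fit(datasets, extra_starts=extra_starts)
    return model.result_


@dataclass
class KcaComparison:
    group_names: list
    F: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p_raw, p_sidak


def compare_kca(groups: dict) -> KcaComparison:
    """One-way ANOVA over per-group K values plus Šidák-adjusted pairwise t tests.

    The post hoc is all-pairs pooled-variance t tests with the Šidák
    family-wise adjustment p_adj = 1 − (1 − p)^m over the m pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    F, p = stats.f_oneway(*arrays)
    pairs = list(itertools.combinations(range(len(names)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        t, praw = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "t": float(t),
                "p_raw": float(praw),
                "p_sidak": float(1.0 - (1.0 - praw) ** m),
            }
        )
    return KcaComparison(
        group_names=names,
        F=float(F),
        p=float(p),
        pairwise=pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_raw", "p_sidak"]),
    )
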