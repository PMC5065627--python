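"""Random-parameter oscillation screen for the simplified clock models.

The screen draws kinetic parameter sets log-uniformly, simulates the
wild type and the lwd1 lwd2 mutant for each set, and accepts a set only
when both genotypes show sustained oscillation of the CCA1 reporter.
Accepted sets are then re-simulated under representative hypomorphic
perturbations (cca1, prr9, toc1) and each mutant period is rescaled so
the set's wild-type period reads exactly 24 h.

Simulation inside the screen uses a fixed-step RK4 integrator compiled
with numba so that screens of 10^5–10^6 parameter sets run on one CPU
in minutes; trajectories that blow up are flagged NON_INTEGRABLE and
rejected.  The adaptive-solver path in :mod:`lwdclock.network` serves
as an independent cross-check on accepted sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np
from numba import njit

from .network import (
    MODEL_I,
    MODEL_II,
    GeneNetworkModel,
    Trace,
    UnknownVariantError,
    build_model,
)

REPORTER = "CCA1"

# Parameter layout used by the fast kernels (Model I ignores the last two).
PARAM_NAMES_II = (
    "v_CCA1", "v_PRR9", "v_TOC1", "v_LWD1",
    "d_CCA1", "d_PRR9", "d_TOC1", "d_LWD1",
    "K_CCA1_TOC1", "K_TOC1_CCA1", "K_PRR9_CCA1", "K_TOC1_PRR9",
    "a_CCA1_PRR9", "K_CCA1_PRR9",
    "a_PRR9_LWD1", "K_PRR9_LWD1",
    "a_LWD1_PRR9", "K_LWD1_PRR9",
    "a_LWD1_CCA1", "K_LWD1_CCA1",
)
PARAM_NAMES_I = PARAM_NAMES_II[:-2]

# Rejection / verdict reasons
OK = "OK"
NO_PEAKS = "NO_PEAKS"
TOO_FEW_CYCLES = "TOO_FEW_CYCLES"
DAMPED_OR_GROWING = "DAMPED_OR_GROWING"
LOW_AMPLITUDE = "LOW_AMPLITUDE"
PERIOD_OUT_OF_BOUNDS = "PERIOD_OUT_OF_BOUNDS"
NON_INTEGRABLE = "NON_INTEGRABLE"
REPORTER_NOT_REDUCED = "REPORTER_NOT_REDUCED"


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter (low, high) bounds sampled log-uniformly."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")

    @classmethod
    def default(cls, variant: str) -> "ParameterRanges":
        """Class-wide default bounds, log-uniform: production v in
        [0.5, 50], degradation d in [0.1, 2] (half-lives of 0.35-7 time
        units), activation strength a in [1, 100] (2- to 101-fold
        boosts) and half-saturation K in [0.05, 5], all around an O(1)
        concentration scale.  Two-decade spans keep a desk-scale screen
        inside the oscillatory regime of the repressilator; time units
        are dimensionless here and are normalised to a 24 h wild-type
        period downstream."""
        names = _param_names(variant)
        per_class = {"v": (0.5, 50.0), "a": (1.0, 100.0),
                     "d": (0.1, 2.0), "K": (0.05, 5.0)}
        return cls({n: per_class[n[0]] for n in names})

    @classmethod
    def wide(cls, variant: str) -> "ParameterRanges":
        """Four-decade exploratory bounds (much lower acceptance rate)."""
        names = _param_names(variant)
        per_class = {"v": (1e-2, 1e2), "a": (1e-2, 1e2),
                     "d": (1e-2, 1e1), "K": (1e-2, 1e2)}
        return cls({n: per_class[n[0]] for n in names})

    def arrays(self, names) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return lo, hi


def _param_names(variant: str):
    if variant == MODEL_I:
        return PARAM_NAMES_I
    if variant == MODEL_II:
        return PARAM_NAMES_II
    raise UnknownVariantError(f"unknown model variant: {variant!r}")


def sample_parameters(ranges: ParameterRanges, n: int, seed: int):
    """Yield ``n`` parameter dicts drawn log-uniformly (streaming)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    names = tuple(ranges.bounds)
    rng = np.random.default_rng(seed)
    lo, hi = ranges.arrays(names)
    llo, lhi = np.log(lo), np.log(hi)
    chunk = 4096
    done = 0
    while done < n:
        m = min(chunk, n - done)
        u = rng.random((m, len(names)))
        vals = np.exp(llo + u * (lhi - llo))
        vals[:, lo == hi] = lo[lo == hi]  # degenerate intervals are exact
        for row in vals:
            yield dict(zip(names, row))
        done += m


def _sample_matrix(rng, lo, hi, n) -> np.ndarray:
    """Matrix form of the same sampling law (row-major: identical stream)."""
    u = rng.random((n, lo.size))
    vals = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    vals[:, lo == hi] = lo[lo == hi]
    return vals


# ---------------------------------------------------------------------------
# Fast fixed-step simulation kernels


@njit(cache=True, fastmath=True)
def _rhs4(x0, x1, x2, x3, p, dose0, dose1, dose2, dose3, model2):
    # species: 0 CCA1, 1 PRR9, 2 TOC1, 3 LWD1; Hill exponent 2
    y0 = x0 if x0 > 0.0 else 0.0
    y1 = x1 if x1 > 0.0 else 0.0
    y2 = x2 if x2 > 0.0 else 0.0
    y3 = x3 if x3 > 0.0 else 0.0
    s0 = y0 * y0
    s1 = y1 * y1
    s2 = y2 * y2
    s3 = y3 * y3
    K_ct = p[8] * p[8]
    K_tc = p[9] * p[9]
    K_pc = p[10] * p[10]
    K_tp = p[11] * p[11]
    K_cp = p[13] * p[13]
    K_pl = p[15] * p[15]
    K_lp = p[17] * p[17]
    f_cca1 = 1.0
    if model2:
        K_lc = p[19] * p[19]
        f_cca1 = 1.0 + p[18] * s3 / (K_lc + s3)
    d0 = (dose0 * p[0] * (K_pc / (K_pc + s1)) * (K_tc / (K_tc + s2)) * f_cca1
          - p[4] * y0)
    d1 = (dose1 * p[1] * (K_tp / (K_tp + s2))
          * (1.0 + p[12] * s0 / (K_cp + s0) + p[16] * s3 / (K_lp + s3))
          - p[5] * y1)
    d2 = dose2 * p[2] * (K_ct / (K_ct + s0)) - p[6] * y2
    d3 = dose3 * p[3] * (1.0 + p[14] * s1 / (K_pl + s1)) - p[7] * y3
    return d0, d1, d2, d3


@njit(cache=True, fastmath=True)
def _simulate_batch(P, model2, doses, t_end, dt, rec_start_step, rec_every, out, ok):
    """RK4-integrate every row of P, recording the CCA1 channel.

    out: (N, n_rec) records CCA1 from step rec_start_step, every
    rec_every steps.  ok[i] is cleared when the trajectory blows up.
    """
    N = P.shape[0]
    n_steps = int(round(t_end / dt))
    n_rec = out.shape[1]
    for i in range(N):
        p = P[i]
        x0 = 0.1
        x1 = 0.1
        x2 = 0.1
        x3 = 0.1
        good = True
        r = 0
        for step in range(n_steps + 1):
            if step >= rec_start_step and (step - rec_start_step) % rec_every == 0:
                if r < n_rec:
                    out[i, r] = x0
                    r += 1
            if step == n_steps:
                break
            a0, a1, a2, a3 = _rhs4(x0, x1, x2, x3, p, doses[0], doses[1], doses[2], doses[3], model2)
            b0, b1, b2, b3 = _rhs4(x0 + 0.5 * dt * a0, x1 + 0.5 * dt * a1,
                                   x2 + 0.5 * dt * a2, x3 + 0.5 * dt * a3,
                                   p, doses[0], doses[1], doses[2], doses[3], model2)
            c0, c1, c2, c3 = _rhs4(x0 + 0.5 * dt * b0, x1 + 0.5 * dt * b1,
                                   x2 + 0.5 * dt * b2, x3 + 0.5 * dt * b3,
                                   p, doses[0], doses[1], doses[2], doses[3], model2)
            e0, e1, e2, e3 = _rhs4(x0 + dt * c0, x1 + dt * c1,
                                   x2 + dt * c2, x3 + dt * c3,
                                   p, doses[0], doses[1], doses[2], doses[3], model2)
            x0 += dt * (a0 + 2 * b0 + 2 * c0 + e0) / 6.0
            x1 += dt * (a1 + 2 * b1 + 2 * c1 + e1) / 6.0
            x2 += dt * (a2 + 2 * b2 + 2 * c2 + e2) / 6.0
            x3 += dt * (a3 + 2 * b3 + 2 * c3 + e3) / 6.0
            if x0 < 0.0:
                x0 = 0.0
            if x1 < 0.0:
                x1 = 0.0
            if x2 < 0.0:
                x2 = 0.0
            if x3 < 0.0:
                x3 = 0.0
            if not (math.isfinite(x0) and math.isfinite(x1)
                    and math.isfinite(x2) and math.isfinite(x3)) or x0 > 1e12:
                good = False
                break
        if not good:
            ok[i] = False
            for rr in range(r, n_rec):
                out[i, rr] = np.nan


@njit(cache=True)
def _peak_metrics(y, dt_rec):
    """Peak-based oscillation metrics for one recorded series.

    Returns (n_peaks, period, ratio_min, ratio_max, rel_amplitude,
    damping_ratio).  Peak times/heights use quadratic interpolation
    around grid maxima.
    """
    n = y.size
    max_pk = 128
    pk_t = np.empty(max_pk)
    pk_h = np.empty(max_pk)
    npk = 0
    tr_h = np.empty(max_pk)
    ntr = 0
    mean = 0.0
    for j in range(n):
        if not math.isfinite(y[j]):
            return 0, np.nan, np.nan, np.nan, np.nan, np.nan
        mean += y[j]
    mean /= n
    for j in range(1, n - 1):
        if y[j] >= y[j - 1] and y[j] > y[j + 1] and npk < max_pk:
            denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
            if denom < 0.0:
                off = 0.5 * (y[j - 1] - y[j + 1]) / denom
                h = y[j] - 0.25 * (y[j - 1] - y[j + 1]) * off
            else:
                off = 0.0
                h = y[j]
            pk_t[npk] = (j + off) * dt_rec
            pk_h[npk] = h
            npk += 1
        if y[j] <= y[j - 1] and y[j] < y[j + 1] and ntr < max_pk:
            denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
            if denom > 0.0:
                off = 0.5 * (y[j - 1] - y[j + 1]) / denom
                h = y[j] - 0.25 * (y[j - 1] - y[j + 1]) * off
            else:
                h = y[j]
            tr_h[ntr] = h
            ntr += 1
    if npk < 2:
        return npk, np.nan, np.nan, np.nan, np.nan, np.nan
    period = (pk_t[npk - 1] - pk_t[0]) / (npk - 1)
    # amplitude ratios are measured above the series mean, so a slowly
    # damped oscillation on a high baseline is still seen as damped
    rmin = 1e300
    rmax = -1e300
    for k in range(npk - 1):
        if pk_h[k] - mean > 0.0:
            ratio = (pk_h[k + 1] - mean) / (pk_h[k] - mean)
        else:
            ratio = np.nan
        if ratio < rmin:
            rmin = ratio
        if ratio > rmax:
            rmax = ratio
    mean_pk = 0.0
    for k in range(npk):
        mean_pk += pk_h[k]
    mean_pk /= npk
    if ntr > 0:
        mean_tr = 0.0
        for k in range(ntr):
            mean_tr += tr_h[k]
        mean_tr /= ntr
    else:
        mean_tr = mean
    rel_amp = (mean_pk - mean_tr) / mean if mean > 0.0 else 0.0
    damping = pk_h[npk - 1] / pk_h[0] if pk_h[0] > 0.0 else np.nan
    return npk, period, rmin, rmax, rel_amp, damping


@njit(cache=True)
def _metrics_batch(out, dt_rec, npks, periods, rmins, rmaxs, relamps, damps):
    for i in range(out.shape[0]):
        npk, per, rmin, rmax, ra, dmp = _peak_metrics(out[i], dt_rec)
        npks[i] = npk
        periods[i] = per
        rmins[i] = rmin
        rmaxs[i] = rmax
        relamps[i] = ra
        damps[i] = dmp


# ---------------------------------------------------------------------------
# Oscillation criteria and assessment


@dataclass(frozen=True)
class OscillationCriteria:
    """Acceptance criteria for calling a trace oscillatory.

    A trace passes when, after discarding the transient, the reporter
    shows at least ``min_cycles`` complete peak-to-peak cycles, every
    successive peak-height ratio lies in ``peak_ratio_band`` (i.e. the
    oscillation is neither damped nor growing), the relative amplitude
    (mean peak minus mean trough, over the series mean) is at least
    ``min_relative_amplitude``, and the peak-interval period falls
    inside ``period_bounds`` when bounds are given.
    """

    min_cycles: int = 5
    peak_ratio_band: tuple[float, float] = (0.95, 1.05)
    min_relative_amplitude: float = 0.1
    period_bounds: tuple[float, float] | None = None
    transient: float = 120.0

    def __post_init__(self):
        if self.min_cycles < 3:
            raise ValueError("min_cycles must be >= 3")
        lo, hi = self.peak_ratio_band
        if not (0 < lo <= hi < 2):
            raise ValueError("peak_ratio_band must lie within (0, 2)")
        if not self.min_relative_amplitude > 0:
            raise ValueError("min_relative_amplitude must be > 0")


@dataclass(frozen=True)
class OscillationVerdict:
    is_oscillatory: bool
    reason: str
    n_peaks: int
    period: float
    relative_amplitude: float
    damping_ratio: float


def _verdict(npk, period, rmin, rmax, relamp, damping, criteria, integrable=True):
    if not integrable:
        return OscillationVerdict(False, NON_INTEGRABLE, 0, np.nan, np.nan, np.nan)
    if npk < 2:
        return OscillationVerdict(False, NO_PEAKS, int(npk), np.nan, np.nan, np.nan)
    if npk < criteria.min_cycles + 1:
        return OscillationVerdict(False, TOO_FEW_CYCLES, int(npk), period, relamp, damping)
    lo, hi = criteria.peak_ratio_band
    if not (rmin >= lo and rmax <= hi):
        return OscillationVerdict(False, DAMPED_OR_GROWING, int(npk), period, relamp, damping)
    if not relamp >= criteria.min_relative_amplitude:
        return OscillationVerdict(False, LOW_AMPLITUDE, int(npk), period, relamp, damping)
    if criteria.period_bounds is not None:
        plo, phi = criteria.period_bounds
        if not (plo <= period <= phi):
            return OscillationVerdict(
                False, PERIOD_OUT_OF_BOUNDS, int(npk), period, relamp, damping
            )
    return OscillationVerdict(True, OK, int(npk), period, relamp, damping)


def assess_oscillation(
    trace: Trace,
    criteria: OscillationCriteria = OscillationCriteria(),
    species: str = REPORTER,
) -> OscillationVerdict:
    """Apply the oscillation criteria to one trace's reporter channel."""
    m = trace.time >= criteria.transient
    y = np.ascontiguousarray(trace.channel(species)[m], dtype=float)
    t = trace.time[m]
    if y.size < 8:
        raise ValueError("trace too short after transient discard")
    dt_rec = float(t[1] - t[0])
    npk, per, rmin, rmax, ra, dmp = _peak_metrics(y, dt_rec)
    return _verdict(npk, per, rmin, rmax, ra, dmp, criteria,
                    integrable=bool(np.all(np.isfinite(y))))


# ---------------------------------------------------------------------------
# The screen itself


@dataclass
class ScreenResult:
    variant: str
    n_sampled: int
    n_accepted: int
    seed: int
    param_names: tuple[str, ...]
    accepted_params: np.ndarray  # (n_accepted, n_params)
    wt_periods: np.ndarray  # unnormalised screen-time periods
    lwd_periods: np.ndarray
    wt_relamps: np.ndarray
    wt_levels: np.ndarray = field(default_factory=lambda: np.empty(0))
    lwd_levels: np.ndarray = field(default_factory=lambda: np.empty(0))
    rejection_tallies: dict[str, int] = field(default_factory=dict)
    criteria: OscillationCriteria = OscillationCriteria()
    t_end: float = 360.0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_sampled if self.n_sampled else 0.0

    def accepted_dicts(self):
        return [dict(zip(self.param_names, row)) for row in self.accepted_params]

    def accepted_to_csv(self, path) -> None:
        """One row per accepted set: parameters plus screen metrics."""
        import pandas as pd

        df = pd.DataFrame(self.accepted_params, columns=list(self.param_names))
        df["wt_period"] = self.wt_periods
        df["lwd1lwd2_period"] = self.lwd_periods
        df["wt_relative_amplitude"] = self.wt_relamps
        df.to_csv(path, index=False)

    def to_json(self) -> str:
        doc = {
            "variant": self.variant,
            "n_sampled": self.n_sampled,
            "n_accepted": self.n_accepted,
            "seed": self.seed,
            "param_names": list(self.param_names),
            "accepted_params": self.accepted_params.tolist(),
            "wt_periods": self.wt_periods.tolist(),
            "lwd_periods": self.lwd_periods.tolist(),
            "wt_relamps": self.wt_relamps.tolist(),
            "wt_levels": self.wt_levels.tolist(),
            "lwd_levels": self.lwd_levels.tolist(),
            "rejection_tallies": self.rejection_tallies,
            "t_end": self.t_end,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ScreenResult":
        doc = json.loads(text)
        return cls(
            variant=doc["variant"],
            n_sampled=doc["n_sampled"],
            n_accepted=doc["n_accepted"],
            seed=doc["seed"],
            param_names=tuple(doc["param_names"]),
            accepted_params=np.array(doc["accepted_params"], dtype=float).reshape(
                doc["n_accepted"], len(doc["param_names"])
            ),
            wt_periods=np.array(doc["wt_periods"], dtype=float),
            lwd_periods=np.array(doc["lwd_periods"], dtype=float),
            wt_relamps=np.array(doc["wt_relamps"], dtype=float),
            wt_levels=np.array(doc.get("wt_levels", []), dtype=float),
            lwd_levels=np.array(doc.get("lwd_levels", []), dtype=float),
            rejection_tallies=doc.get("rejection_tallies", {}),
            t_end=doc.get("t_end", 360.0),
        )


_WT_DOSES = np.ones(4)
_LWD_NULL_DOSES = np.array([1.0, 1.0, 1.0, 0.0])

_DT = 0.1  # integration step (screen time units)
_DT_REC = 0.5  # recording interval for peak analysis


def _run_batch(P, model2, doses, t_end, transient):
    n_rec = int(round((t_end - transient) / _DT_REC)) + 1
    out = np.empty((P.shape[0], n_rec))
    ok = np.ones(P.shape[0], dtype=np.bool_)
    _simulate_batch(
        np.ascontiguousarray(P), model2, doses, t_end, _DT,
        int(round(transient / _DT)), int(round(_DT_REC / _DT)), out, ok,
    )
    npks = np.empty(P.shape[0], dtype=np.int64)
    periods = np.empty(P.shape[0])
    rmins = np.empty(P.shape[0])
    rmaxs = np.empty(P.shape[0])
    relamps = np.empty(P.shape[0])
    damps = np.empty(P.shape[0])
    _metrics_batch(out, _DT_REC, npks, periods, rmins, rmaxs, relamps, damps)
    means = out.mean(axis=1)  # NaN for non-integrable rows
    return ok, npks, periods, rmins, rmaxs, relamps, means


def _accept_mask(ok, npks, periods, rmins, rmaxs, relamps, criteria):
    m = ok & (npks >= criteria.min_cycles + 1)
    lo, hi = criteria.peak_ratio_band
    with np.errstate(invalid="ignore"):
        m &= (rmins >= lo) & (rmaxs <= hi)
        m &= relamps >= criteria.min_relative_amplitude
        if criteria.period_bounds is not None:
            plo, phi = criteria.period_bounds
            m &= (periods >= plo) & (periods <= phi)
    return m


def _tally(tallies, ok, npks, rmins, rmaxs, relamps, criteria, considered):
    """Classify rejection reasons for the traces in `considered`."""
    lo, hi = criteria.peak_ratio_band
    non_int = considered & ~ok
    tallies[NON_INTEGRABLE] = tallies.get(NON_INTEGRABLE, 0) + int(non_int.sum())
    rest = considered & ok
    few = rest & (npks < criteria.min_cycles + 1)
    tallies[TOO_FEW_CYCLES] = tallies.get(TOO_FEW_CYCLES, 0) + int(few.sum())
    rest &= ~few
    with np.errstate(invalid="ignore"):
        damped = rest & ~((rmins >= lo) & (rmaxs <= hi))
    tallies[DAMPED_OR_GROWING] = tallies.get(DAMPED_OR_GROWING, 0) + int(damped.sum())
    rest &= ~damped
    with np.errstate(invalid="ignore"):
        lowamp = rest & ~(relamps >= criteria.min_relative_amplitude)
    tallies[LOW_AMPLITUDE] = tallies.get(LOW_AMPLITUDE, 0) + int(lowamp.sum())


def screen_variant(
    variant: str,
    ranges: ParameterRanges | None = None,
    n: int = 10000,
    seed: int = 0,
    criteria: OscillationCriteria = OscillationCriteria(),
    t_end: float = 360.0,
    chunk: int = 8192,
    require_reduced_reporter: bool = True,
) -> ScreenResult:
    """Screen ``n`` random parameter sets for the lwd1 lwd2 phenotype.

    A set is accepted when (i) the wild type oscillates, (ii) the
    lwd1lwd2 mutant oscillates, and (iii) with
    ``require_reduced_reporter`` (the default), the mean CCA1 level in
    lwd1lwd2 is lower than in the wild type — the defining experimental
    phenotype of the double mutant.  Model I can essentially never meet
    (iii), because losing LWD1 lowers PRR9 and thereby *de-represses*
    CCA1; Model II's direct LWD1->CCA1 activation reverses the sign.

    Deterministic given (variant, ranges, n, seed, criteria): parameters
    are drawn from a single seeded stream in row-major order, so the
    chunk size does not affect which sets are drawn.
    """
    names = _param_names(variant)
    if ranges is None:
        ranges = ParameterRanges.default(variant)
    if set(ranges.bounds) != set(names):
        raise ValueError("ranges must cover exactly the model's parameters")
    model2 = variant == MODEL_II
    lo, hi = ranges.arrays(names)
    rng = np.random.default_rng(seed)

    acc = {k: [] for k in ("rows", "wt_per", "lwd_per", "relamp", "wt_lvl", "lwd_lvl")}
    tallies: dict[str, int] = {}
    done = 0
    while done < n:
        m = min(chunk, n - done)
        P = _sample_matrix(rng, lo, hi, m)
        if not model2:
            P = np.hstack([P, np.ones((m, 2))])  # pad; kernel ignores cols 16-17
        ok_w, npk_w, per_w, rmin_w, rmax_w, ra_w, lvl_w = _run_batch(
            P, model2, _WT_DOSES, t_end, criteria.transient
        )
        mask_w = _accept_mask(ok_w, npk_w, per_w, rmin_w, rmax_w, ra_w, criteria)
        _tally(tallies, ok_w, npk_w, rmin_w, rmax_w, ra_w, criteria,
               np.ones(m, dtype=bool))
        if mask_w.any():
            idx = np.flatnonzero(mask_w)
            ok_l, npk_l, per_l, rmin_l, rmax_l, ra_l, lvl_l = _run_batch(
                P[idx], model2, _LWD_NULL_DOSES, t_end, criteria.transient
            )
            mask_l = _accept_mask(ok_l, npk_l, per_l, rmin_l, rmax_l, ra_l, criteria)
            if require_reduced_reporter:
                with np.errstate(invalid="ignore"):
                    reduced = lvl_l < lvl_w[idx]
                tallies[REPORTER_NOT_REDUCED] = tallies.get(
                    REPORTER_NOT_REDUCED, 0
                ) + int((mask_l & ~reduced).sum())
                mask_l &= reduced
            for j, i_local in enumerate(idx):
                if mask_l[j]:
                    acc["rows"].append(P[i_local, : len(names)])
                    acc["wt_per"].append(per_w[i_local])
                    acc["lwd_per"].append(per_l[j])
                    acc["relamp"].append(ra_w[i_local])
                    acc["wt_lvl"].append(lvl_w[i_local])
                    acc["lwd_lvl"].append(lvl_l[j])
        done += m

    n_acc = len(acc["rows"])
    return ScreenResult(
        variant=variant,
        n_sampled=n,
        n_accepted=n_acc,
        seed=seed,
        param_names=names,
        accepted_params=(
            np.array(acc["rows"]) if n_acc else np.empty((0, len(names)))
        ),
        wt_periods=np.array(acc["wt_per"]),
        lwd_periods=np.array(acc["lwd_per"]),
        wt_relamps=np.array(acc["relamp"]),
        wt_levels=np.array(acc["wt_lvl"]),
        lwd_levels=np.array(acc["lwd_lvl"]),
        rejection_tallies=tallies,
        criteria=criteria,
        t_end=t_end,
    )


# ---------------------------------------------------------------------------
# Mutant period analysis


class EmptyScreenError(ValueError):
    """Raised when a period table is requested from an empty screen."""


GENOTYPE_DOSES = {
    "WT": np.ones(4),
    "lwd1lwd2": _LWD_NULL_DOSES,
    "cca1": np.array([0.5, 1.0, 1.0, 1.0]),
    "prr9": np.array([1.0, 0.5, 1.0, 1.0]),
    "toc1": np.array([1.0, 1.0, 0.5, 1.0]),
}


@dataclass
class PeriodDistribution:
    """Normalised period box statistics per genotype (WT period == 24 h)."""

    stats: dict[str, dict[str, float]]
    arrhythmic: dict[str, int]
    n_sets: int

    def to_json(self) -> str:
        return json.dumps(
            {"stats": self.stats, "arrhythmic": self.arrhythmic, "n_sets": self.n_sets},
            indent=2,
        )


def mutant_period_table(
    screen: ScreenResult,
    genotypes=("prr9", "cca1", "toc1"),
    criteria: OscillationCriteria | None = None,
) -> PeriodDistribution:
    """Re-simulate each accepted set under each genotype and box the periods.

    Periods are rescaled per parameter set so the set's wild-type period
    is exactly 24 h; mutants judged arrhythmic under the (relaxed, see
    below) rhythm check are tallied separately and excluded from the box
    statistics.  A mutant only needs a stable measurable rhythm, not the
    full screen acceptance band, so the check here is ≥ 3 cycles with
    peak ratios in [0.75, 1.25].
    """
    if screen.n_accepted < 1:
        raise EmptyScreenError("screen has no accepted parameter sets")
    unknown = set(genotypes) - set(GENOTYPE_DOSES)
    if unknown:
        raise ValueError(f"unknown genotypes: {sorted(unknown)}")
    model2 = screen.variant == MODEL_II
    P = screen.accepted_params
    if P.shape[1] < len(PARAM_NAMES_II):
        pad = len(PARAM_NAMES_II) - P.shape[1]
        P = np.hstack([P, np.ones((P.shape[0], pad))])
    crit = criteria or OscillationCriteria(
        min_cycles=3, peak_ratio_band=(0.75, 1.25),
        min_relative_amplitude=0.02, transient=screen.criteria.transient,
    )
    stats: dict[str, dict[str, float]] = {}
    arrhythmic: dict[str, int] = {}
    for name in genotypes:
        if name == "WT":
            periods = np.full(screen.n_accepted, 24.0)
            arr = 0
        else:
            ok, npk, per, rmin, rmax, ra, _ = _run_batch(
                P, model2, GENOTYPE_DOSES[name], screen.t_end, crit.transient
            )
            mask = _accept_mask(ok, npk, per, rmin, rmax, ra, crit)
            periods = 24.0 * per[mask] / screen.wt_periods[mask]
            arr = int(screen.n_accepted - mask.sum())
        arrhythmic[name] = arr
        if periods.size:
            q1, med, q3 = np.percentile(periods, [25, 50, 75])
            stats[name] = {
                "median": float(med), "q1": float(q1), "q3": float(q3),
                "min": float(periods.min()), "max": float(periods.max()),
                "n": int(periods.size),
            }
        else:
            stats[name] = {"median": np.nan, "q1": np.nan, "q3": np.nan,
                           "min": np.nan, "max": np.nan, "n": 0}
    return PeriodDistribution(stats=stats, arrhythmic=arrhythmic,
                              n_sets=screen.n_accepted)


def simulate_set(
    params: dict[str, float],
    variant: str,
    genotype: str = "WT",
    t_end: float = 360.0,
) -> Trace:
    """Simulate one parameter set with the fast screen integrator,
    returning the full post-transient CCA1 trace on the 0.5-unit grid
    (transient included, from t=0)."""
    names = _param_names(variant)
    P = np.array([[params[n] for n in names]])
    if P.shape[1] < len(PARAM_NAMES_II):
        P = np.hstack([P, np.ones((1, len(PARAM_NAMES_II) - P.shape[1]))])
    n_rec = int(round(t_end / _DT_REC)) + 1
    out = np.empty((1, n_rec))
    ok = np.ones(1, dtype=np.bool_)
    _simulate_batch(
        np.ascontiguousarray(P), variant == MODEL_II,
        GENOTYPE_DOSES[genotype], t_end, _DT, 0, int(round(_DT_REC / _DT)),
        out, ok,
    )
    t = np.arange(n_rec) * _DT_REC
    values = np.full((n_rec, 4), np.nan)
    values[:, 0] = out[0]
    return Trace(t, values, ("CCA1", "PRR9", "TOC1", "LWD1"),
                 metadata={"variant": variant, "genotype": genotype,
                           "integrator": "rk4", "dt": _DT})


def full_model(params: dict[str, float], variant: str) -> GeneNetworkModel:
    """Build a variant model carrying the given parameter values."""
    return build_model(variant).with_parameters(params)
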