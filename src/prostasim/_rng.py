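"""Seeded random-stream plumbing and vectorized hazard-inversion samplers.

All simulation randomness flows through named child streams derived from a
single integer master seed, so that counterfactual arms and alternative
screening strategies share draws (common random numbers) wherever the model
says they should.
"""

from __future__ import annotations

import numpy as np

# Named stream keys. Streams 0-9 belong to the no-screening life history;
# 10+ are screening-specific and never consumed by the counterfactual arm.
STREAM_NATURAL_HISTORY = 0
STREAM_OTHER_CAUSE = 1
STREAM_SURVIVAL = 2
STREAM_CURE = 3
STREAM_SCREEN_BASE = 10  # + test slot index


def child_rng(seed: int, key: int) -> np.random.Generator:
    """Independent generator for stream ``key`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(key),)))


def sample_piecewise_exponential(
    start: np.ndarray,
    edges: np.ndarray,
    rates: np.ndarray,
    u: np.ndarray,
    t_max: float = np.inf,
) -> np.ndarray:
    """Invert a piecewise-constant hazard to an event time, per row.

    Parameters
    ----------
    start : (n,) ages at which each subject's clock starts.
    edges : (k+1,) ascending band edges covering all relevant ages.
    rates : (n, k) or (k,) hazard per year within each band.
    u : (n,) uniforms.
    t_max : hard censoring age; events past it return ``inf``.

    Returns
    -------
    (n,) event ages; ``inf`` where the cumulative hazard is exhausted.
    """
    start = np.asarray(start, dtype=float)
    u = np.asarray(u, dtype=float)
    n = start.shape[0]
    edges = np.asarray(edges, dtype=float)
    k = edges.shape[0] - 1
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (n, k))

    target = -np.log(u)
    lo = np.maximum(edges[:-1][None, :], start[:, None])
    hi = np.minimum(edges[1:][None, :], t_max)
    dur = np.clip(hi - lo, 0.0, None)
    cum = np.cumsum(rates * dur, axis=1)
    # first band where cumulative hazard reaches the target
    reached = cum >= target[:, None]
    idx = np.argmax(reached, axis=1)
    ok = reached.any(axis=1)
    idx_safe = np.where(ok, idx, 0)
    rows = np.arange(n)
    prev = np.where(idx_safe > 0, cum[rows, idx_safe - 1], 0.0)
    r = rates[rows, idx_safe]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lo[rows, idx_safe] + (target - prev) / r
    return np.where(ok, t, np.inf)


def sample_expgrowth_piecewise(
    onset: np.ndarray,
    level0: np.ndarray,
    growth: np.ndarray,
    coef: float,
    edges: np.ndarray,
    mult: np.ndarray,
    u: np.ndarray,
    t_max: float = np.inf,
) -> np.ndarray:
    """Invert a hazard proportional to an exponentially growing level.

    hazard(a) = mult(a) * coef * level0 * exp(growth * (a - onset)), a >= onset,
    where ``mult`` is piecewise constant over age bands ``edges``. Used for
    PSA-linked clinical-diagnosis times. Growth rates very close to zero fall
    back to the piecewise-constant-hazard path.
    """
    onset = np.asarray(onset, dtype=float)
    level0 = np.asarray(level0, dtype=float)
    n = onset.shape[0]
    growth = np.broadcast_to(np.asarray(growth, dtype=float), (n,)).copy()
    edges = np.asarray(edges, dtype=float)
    k = edges.shape[0] - 1
    mult = np.asarray(mult, dtype=float)

    out = np.full(n, np.inf)
    flat = np.abs(growth) < 1e-9
    if flat.any():
        rates = mult[None, :] * (coef * level0[flat])[:, None]
        out[flat] = sample_piecewise_exponential(
            onset[flat], edges, rates, np.asarray(u)[flat], t_max=t_max
        )
    grow = ~flat
    if grow.any():
        on = onset[grow]
        b = growth[grow]
        amp = coef * level0[grow] / b  # hazard integral amplitude
        target = -np.log(np.asarray(u)[grow])
        lo = np.maximum(edges[:-1][None, :], on[:, None])
        hi = np.minimum(edges[1:][None, :], t_max)
        hi = np.maximum(hi, lo)  # empty segments contribute zero
        # cumulative hazard over each segment, exact for exponential growth
        e_lo = np.exp(b[:, None] * (lo - on[:, None]))
        e_hi = np.exp(b[:, None] * (hi - on[:, None]))
        seg = mult[None, :] * amp[:, None] * (e_hi - e_lo)
        cum = np.cumsum(seg, axis=1)
        reached = cum >= target[:, None]
        idx = np.argmax(reached, axis=1)
        ok = reached.any(axis=1)
        idx_safe = np.where(ok, idx, 0)
        rows = np.arange(on.shape[0])
        prev = np.where(idx_safe > 0, cum[rows, idx_safe - 1], 0.0)
        rem = target - prev
        m = mult[idx_safe]
        base = e_lo[rows, idx_safe]
        # solve m*amp*(e^{b s} - base) = rem for s = a - onset
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.log(base + rem / (m * amp[rows])) / b
        t = on + s
        out_g = np.where(ok & (t <= t_max), t, np.inf)
        out[grow] = out_g
    return out
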