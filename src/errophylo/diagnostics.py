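"""MCMC trace diagnostics: HPD intervals and effective sample size."""

from __future__ import annotations

import math

import numpy as np


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ⌈mass·N⌉ sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def ess(samples, max_lag: int | None = None) -> float:
    """Effective sample size via the integrated autocorrelation time.

    The autocorrelation function is summed until it first drops below
    zero (the truncation used by common trace analysers); ESS = N / τ
    with τ = 1 + 2 Σ ρ_k.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for an ESS estimate")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    if max_lag is None:
        max_lag = min(n - 1, 2000)
    # autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:max_lag + 1].real / n
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, max_lag + 1):
        if rho[k] < 0:
            break
        tau += 2.0 * rho[k]
    return float(min(n, n / tau))
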