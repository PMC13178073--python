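"""Interaction-entropy estimator.

The entropic penalty of binding is estimated from the fluctuations of the
receptor-ligand interaction energy along the trajectory:

    -T*dS = kB*T * ln < exp(beta * dE_int) >,

where dE_int = E_int(frame) - <E_int> and the bracket averages over frames.
The exponential average is evaluated in log space (logsumexp), since
beta*|dE| can exceed the floating-point exponent range. By Jensen's
inequality the estimator is nonnegative; it grows roughly as
sigma^2/(2*kB*T) for Gaussian fluctuations, which makes it notoriously
sensitive to sampling once sigma exceeds a few kB*T — the convergence
diagnostics below exist for exactly that reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE
from .errors import PoseDeltaError

#: fluctuation level above which the exponential average is deemed
#: unreliable at the given temperature (reliability heuristic)
SIGMA_RELIABILITY_FACTOR = 2.0


@dataclass(frozen=True)
class EntropyEstimate:
    minus_t_delta_s: float  # kcal/mol, >= 0
    temperature: float  # K
    n_samples: int
    sigma_e: float  # SD of E_int, kcal/mol
    converged: bool


@dataclass(frozen=True)
class ConvergenceReport:
    block_estimates: np.ndarray  # one -T*dS per contiguous block
    cumulative: np.ndarray  # -T*dS over the first k samples, k = 2..n
    full: EntropyEstimate
    converged: bool


def interaction_entropy(e_int_samples: np.ndarray,
                        temperature: float = DEFAULT_TEMPERATURE) -> EntropyEstimate:
    """-T*dS (kcal/mol) from interaction-energy samples."""
    e = np.asarray(e_int_samples, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise PoseDeltaError(f"need >= 2 interaction-energy samples, got {e.size}")
    if not np.all(np.isfinite(e)):
        idx = int(np.flatnonzero(~np.isfinite(e))[0])
        raise PoseDeltaError(f"non-finite interaction energy at sample index {idx}")
    if not temperature > 0:
        raise PoseDeltaError(f"temperature must be positive, got {temperature}")
    kbt = BOLTZMANN_KCAL * temperature
    beta = 1.0 / kbt
    de = e - e.mean()
    log_avg = logsumexp(beta * de) - np.log(e.size)
    value = max(0.0, float(kbt * log_avg))  # clamp -0.0 / tiny negative roundoff
    sigma = float(np.std(de, ddof=0))
    return EntropyEstimate(
        minus_t_delta_s=value,
        temperature=temperature,
        n_samples=int(e.size),
        sigma_e=sigma,
        converged=sigma <= SIGMA_RELIABILITY_FACTOR * kbt,
    )


def entropy_convergence(e_int_samples: np.ndarray,
                        temperature: float = DEFAULT_TEMPERATURE,
                        n_blocks: int = 5) -> ConvergenceReport:
    """Block and cumulative convergence diagnostics for the estimator.

    The report is flagged non-converged when the full-sample sigma heuristic
    fails or when contiguous-block estimates disagree by more than 2*kB*T —
    the signature of an exponential average dominated by a few frames.
    """
    e = np.asarray(e_int_samples, dtype=float)
    if n_blocks < 2:
        raise PoseDeltaError(f"n_blocks must be >= 2, got {n_blocks}")
    if e.size < 2 * n_blocks:
        raise PoseDeltaError(
            f"need >= {2 * n_blocks} samples for {n_blocks} blocks, got {e.size}"
        )
    full = interaction_entropy(e, temperature)
    blocks = np.array_split(e, n_blocks)
    block_est = np.asarray(
        [interaction_entropy(b, temperature).minus_t_delta_s for b in blocks]
    )
    cumulative = np.asarray(
        [interaction_entropy(e[: k + 1], temperature).minus_t_delta_s
         for k in range(1, e.size)]
    )
    kbt = BOLTZMANN_KCAL * temperature
    spread_ok = (block_est.max() - block_est.min()) <= 2.0 * kbt
    return ConvergenceReport(
        block_estimates=block_est,
        cumulative=cumulative,
        full=full,
        converged=bool(full.converged and spread_ok),
    )
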