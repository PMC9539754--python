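"""Small shared utilities: power arithmetic and seed derivation."""

from __future__ import annotations

import numpy as np
from scipy import stats


def power_two_sample_t(
    effect_size: float,
    n_per_group: int,
    alpha: float = 0.05,
) -> float:
    """Power of a two-sided two-sample t-test (equal n, equal variance).

    ``effect_size`` is Cohen's d (difference in units of the common SD).
    Uses the noncentral t distribution: with ncp = d * sqrt(n/2) and
    df = 2n - 2, power = P(|T_ncp| > t_crit).  An RNA-seq design with
    n = 6 per group detects d = 2 with ~90% power at alpha = 0.05.
    """
    df = 2 * n_per_group - 2
    ncp = effect_size * np.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2^31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
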