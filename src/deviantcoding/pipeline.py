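"""Convenience composition of the analysis stages.

These helpers wire the library modules together the way the CLI and batch
scripts use them: subset to the driven population, build position-matched
sets, compute change coefficients and their surrogate null, and run the
broadening test.
"""

from __future__ import annotations

import numpy as np

from .change_coding import (broadening_test, change_coefficient,
                            grouped_deviant_effect, surrogate_population)
from .datatypes import AnalysisConfig
from .stimulus import deflection_sets, histogram_match_positions
from .units import CountTensor


def run_change_coding(
    counts: CountTensor,
    trains,
    driven_mask: np.ndarray,
    cfg: AnalysisConfig | None = None,
    seed=0,
) -> dict:
    """Change-coefficient analysis for one condition's driven population.

    Returns a dict with the coefficient set, surrogate, broadening stats,
    and the grouped (sign-ignoring) deviant effect.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sub = counts.subset_units(np.asarray(driven_mask))
    dev, base = deflection_sets(trains)
    matched = histogram_match_positions(dev, base, rng)
    coeffs = change_coefficient(sub, trains, matched)
    surr = surrogate_population(sub, trains, n_draws=cfg.surrogate_draws,
                                seed=rng, matched=matched)
    stats = broadening_test(coeffs, surr, cfg, seed=rng)
    grouped_diff, grouped_p, grouped_ci = grouped_deviant_effect(
        sub, trains, matched, seed=rng, n_boot=cfg.surrogate_draws)
    return {
        "coefficients": coeffs,
        "surrogate": surr,
        "broadening": stats,
        "grouped_effect": {"per_unit": grouped_diff, "p": grouped_p,
                           "ci_median": grouped_ci},
        "matched": matched,
    }
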