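"""Monte-Carlo validation experiments for the whole pipeline.

These experiments quantify, over many simulated screens, the three
operating characteristics that matter for an analysis of this kind:

* **recovery** — how reliably COMPARE places planted response-correlated
  genes in the correctly signed candidate list, and how much independent
  background leaks in;
* **cross-resistance detection** — how often the within-family compound
  correlations implied by the latent-factor model are called at the
  conventional ``|r| > 0.6``, ``p <= 0.05`` rule;
* **calibration** — whether the final chi-square test keeps its nominal
  type-I error when expression carries no signal at all.

The null-calibration experiment clusters the lines on *all* probes
(COMPARE threshold 0): under the null essentially no probe ever clears a
positive threshold, so a selection-then-test composition either aborts
for lack of candidates or conditions on a chance selection, and the
calibration question is only well-posed when the clustering is
independent of the response — which holds for any fixed gene set under
the null.  See the methods note for the full argument.

Per-replicate seeds are derived from a single base seed, so every
experiment is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .association import predict_response
from .compare import compare
from .correlation import cross_resistance_matrix
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "planted_recovery_experiment",
    "within_family_detection_experiment",
    "null_calibration_experiment",
    "null_simulation_config",
]


def _seeds(base_seed: int, n: int) -> list[int]:
    # derived replicate seeds, kept well below 2**31
    return [(base_seed * 100_003 + i) % 2_147_483_647 for i in range(n)]


def null_simulation_config(seed: int, n_genes: int = 40) -> SimulationConfig:
    """Generator settings with no planted genes and no family factor.

    The 40-gene default mirrors the size of the candidate set the real
    screen produced, so the null clustering operates on a gene panel of
    comparable width.
    """
    return SimulationConfig(
        seed=seed,
        families=(("drug", 8, 0.0),),
        noise_sd=1.0,
        mu_range=(-6.5, -5.5),
        n_background_genes=n_genes,
        planted_genes=(),
    )


def planted_recovery_experiment(
    n_seeds: int = 50,
    base_seed: int = 1,
    threshold: float = 0.6,
) -> dict:
    """Fraction of planted genes landing in the correctly signed list.

    Runs the default screen (60 lines, 20 planted genes at rho = 0.8
    among 2000 background genes) ``n_seeds`` times, COMPAREs against the
    first query compound at ``threshold``, and reports the mean recovery
    fraction plus the mean number of background probes contaminating
    the candidate lists.
    """
    recovery, contamination = [], []
    for seed in _seeds(base_seed, n_seeds):
        config = SimulationConfig(seed=seed)
        response, expression, truth = simulate_dataset(config)
        result = compare(
            expression, response, response.compound_ids[0], threshold=threshold
        )
        standard = set(result.standard_list.index)
        reverse = set(result.reverse_list.index)
        hits = 0
        for _, row in truth.iterrows():
            target = standard if row["sign"] > 0 else reverse
            hits += row["probe_id"] in target
        recovery.append(hits / len(truth))
        contamination.append(
            sum(1 for p in standard | reverse if p.startswith("bg_"))
        )
    return {
        "n_seeds": n_seeds,
        "mean_recovery": float(np.mean(recovery)),
        "min_recovery": float(np.min(recovery)),
        "mean_background_contamination": float(np.mean(contamination)),
    }


def within_family_detection_experiment(
    n_seeds: int = 50,
    base_seed: int = 1,
    threshold: float = 0.6,
) -> dict:
    """Detection of factor-model cross-resistance within a compound family.

    The default family loading gives a theoretical within-family
    correlation of 0.7.  For each replicate the all-versus-all grid over
    the 8-compound family is computed and the fraction of the 28
    within-family pairs called cross-resistant (``|r| > threshold``,
    ``p <= 0.05``) recorded; reported are the mean pair detection rate
    and the fraction of replicates in which a majority of pairs is
    detected.
    """
    pair_rates, majorities = [], []
    for seed in _seeds(base_seed, n_seeds):
        config = SimulationConfig(
            seed=seed, families=(("withanolide", 8, np.sqrt(0.7)),)
        )
        response = simulate_dataset(config)[0]
        xres = cross_resistance_matrix(response, threshold=threshold)
        flags = xres.cross_resistant.to_numpy()
        upper = flags[np.triu_indices_from(flags, k=1)]
        pair_rates.append(upper.mean())
        majorities.append(upper.mean() > 0.5)
    return {
        "n_seeds": n_seeds,
        "mean_pair_detection_rate": float(np.mean(pair_rates)),
        "majority_detected_fraction": float(np.mean(majorities)),
    }


def null_calibration_experiment(
    n_seeds: int = 400,
    base_seed: int = 1,
    alpha: float = 0.05,
    k: int = 4,
) -> dict:
    """Type-I error of the composed pipeline under the null generator.

    Every replicate simulates a screen with no planted genes and no
    family factor, runs the full predict-response composition with
    COMPARE threshold 0 (all probes enter the clustering), and tests at
    level ``alpha``.  Reports the rejection rate and the 3-binomial-SD
    band around ``alpha`` it is expected to fall in when the chi-square
    test is calibrated.
    """
    pvalues = []
    for seed in _seeds(base_seed, n_seeds):
        response, expression, _ = simulate_dataset(null_simulation_config(seed))
        results = predict_response(
            expression, response, response.compound_ids[0], threshold=0.0, k=k
        )
        pvalues.append(results.pvalue)
    pvalues = np.array(pvalues)
    rate = float((pvalues <= alpha).mean())
    sd = float(np.sqrt(alpha * (1 - alpha) / n_seeds))
    return {
        "n_seeds": n_seeds,
        "alpha": alpha,
        "rejection_rate": rate,
        "band_low": alpha - 3 * sd,
        "band_high": alpha + 3 * sd,
        "mean_pvalue": float(pvalues.mean()),
    }
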