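"""Published fitted parameter sets for rice panicle-coverage dynamics.

Seventeen treatment conditions from a two-season rice phenotyping study
(field and soil-bin plots, three nitrogen rates, four cultivars, normal and
late transplanting). Each row holds the five parameters of the piecewise
growth-decline curve — K (maximum coverage fraction), g (growth rate per
day), d0 (day of maximum growth rate), a (decline curvature per day^2),
d1 (growth-to-decline transition day) — plus the reported goodness of fit.

These values serve two purposes: spot-check targets for parameter-recovery
tests, and a realistic envelope from which the synthetic-data generator
samples multi-plot scenarios.
"""

from __future__ import annotations

from .piecewise_model import PiecewiseParams

# treatment -> (K, g, d0, a, d1, r_squared)
TREATMENT_TABLE: dict[str, tuple[float, float, float, float, float, float]] = {
    "23-F-0N": (0.2512, 0.2738, 9.9412, 0.0003, 28.0717, 0.9858),
    "23-F-0N-LT": (0.2081, 0.2889, 8.3847, 0.0002, 26.11, 0.9825),
    "23-F-9N": (0.306, 0.2681, 8.6695, 0.0003, 27.0125, 0.9876),
    "23-F-9N-LT": (0.3078, 0.3712, 7.7353, 0.0001, 25.7043, 0.9958),
    "23-S-0N": (0.3272, 0.2658, 9.5009, 0.0003, 28.9899, 0.9926),
    "23-S-18N": (0.3505, 0.2649, 8.2946, 0.0003, 27.4182, 0.9932),
    "23-S-9N": (0.3455, 0.2781, 8.3295, 0.0003, 27.0919, 0.9936),
    "24-F-0N-DJ": (0.2067, 0.3683, 8.5425, 0.0002, 26.3238, 0.9932),
    "24-F-0N-NP": (0.222, 0.3098, 10.311, 0.0001, 29.3876, 0.9967),
    "24-F-0N-SD": (0.1574, 0.2746, 11.0649, 0.0, 31.9771, 0.9918),
    "24-F-0N-SI": (0.211, 0.2103, 13.0975, 0.0, 34.027, 0.9918),
    "24-F-9N-DJ": (0.25, 0.4606, 4.9593, 0.0002, 17.093, 0.9672),
    "24-F-9N-NP": (0.2663, 0.3667, 7.5438, 0.0002, 23.7445, 0.986),
    "24-F-9N-SD": (0.2102, 0.3355, 7.8603, 0.0001, 25.8459, 0.9902),
    "24-F-9N-SI": (0.2782, 0.2695, 8.9365, 0.0002, 28.3735, 0.9905),
    "24-S-0N": (0.193, 0.198, 17.6353, 0.0002, 40.1652, 0.9932),
    "24-S-9N": (0.2293, 0.2053, 14.5728, 0.0002, 37.9843, 0.9908),
    "24-S-18N": (0.2171, 0.206, 16.2943, 0.0003, 38.9029, 0.9923),
}


def treatment_params(treatment: str) -> PiecewiseParams:
    """Return the published parameter set for one treatment code."""
    try:
        K, g, d0, a, d1, _ = TREATMENT_TABLE[treatment]
    except KeyError:
        raise KeyError(
            f"unknown treatment {treatment!r}; known: {sorted(TREATMENT_TABLE)}"
        ) from None
    return PiecewiseParams(K=K, g=g, d0=d0, a=a, d1=d1)


def all_treatment_params() -> dict[str, PiecewiseParams]:
    """All published parameter sets keyed by treatment code."""
    return {name: treatment_params(name) for name in TREATMENT_TABLE}


def parameter_envelope() -> dict[str, tuple[float, float]]:
    """Per-parameter (min, max) range across the published treatments.

    Used as the sampling envelope for realistic synthetic scenarios.
    """
    rows = list(TREATMENT_TABLE.values())
    env = {}
    for i, name in enumerate(("K", "g", "d0", "a", "d1")):
        vals = [r[i] for r in rows]
        env[name] = (min(vals), max(vals))
    return env
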