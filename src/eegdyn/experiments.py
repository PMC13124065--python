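"""Reference synthetic-cohort experiments.

These encode the study conditions the package is validated against: a
four-group lifespan-like cohort (YC, OC, YA, OA) in which the young-adult
group has the slowest, most heterogeneous network switching (longest, most
dispersed dwell times) and children carry more slow-band power. The planted
effects are the generator's operationalization of the inverted-U and
monotonic lifespan trajectories; the experiment checks that the full
pipeline — wavelet phase, sliding CCorr networks, correlation-distance jump
lengths, mc-Task PLS — recovers them.
"""

from __future__ import annotations

import numpy as np

from .pipeline import dataset_features, run_pls
from .synth import SynthSpec, gen_study

#: Planted dwell means (s) per group (YC, OC, YA, OA): children switch
#: network states fastest, young adults slowest; old adults intermediate.
LIFESPAN_DWELL_MEAN = (1.6, 2.1, 3.8, 2.7)
#: Dwell-time coefficients of variation: switching is most dispersed for YA.
LIFESPAN_DWELL_CV = (0.3, 0.4, 0.8, 0.5)
#: Slow-band (2-8 Hz) amplitude gains: children carry more slow power.
LIFESPAN_SLOW_GAIN = (1.5, 1.3, 1.0, 0.9)


def lifespan_cohort_spec(seed: int, subjects_per_group: int = 12,
                         n_conditions: int = 1, n_channels: int = 8,
                         segments: int = 3) -> SynthSpec:
    """A scaled-down lifespan cohort with the planted inverted-U effects."""
    return SynthSpec(
        n_groups=4,
        n_conditions=n_conditions,
        subjects_per_group=subjects_per_group,
        segments_range=(segments, segments),
        n_channels=n_channels,
        n_states=3,
        freqs=(4.0, 10.0),
        snr=3.0,
        dwell_mean_s=LIFESPAN_DWELL_MEAN,
        dwell_cv=LIFESPAN_DWELL_CV,
        slow_gain=LIFESPAN_SLOW_GAIN,
        seed=seed,
    )


def run_lifespan_cohort(seed: int, subjects_per_group: int = 12,
                        n_perm: int = 200, n_boot: int = 300,
                        step_samples: int = 25) -> dict:
    """Generate one cohort, run the switching-dynamics pipeline and PLS.

    Returns group-level mean jump lengths, the fitted PLS model on the
    jump-length block, and whether LV1's bootstrap CIs separate the
    young-adult group from every other group within each condition.
    """
    spec = lifespan_cohort_spec(seed, subjects_per_group)
    dataset = gen_study(spec)
    features = dataset_features(dataset, freqs=spec.freqs,
                                step_samples=step_samples)
    jl = features["jl"]
    mu_cols = [c for c in jl.columns if c.startswith("mu_jl")]
    mu_by_group = (jl[mu_cols].mean(axis=1)
                   .groupby(level="group").mean()
                   .reindex(list(spec.group_labels)))

    model = run_pls(jl, n_perm=n_perm, n_boot=n_boot, seed=seed)
    separated = _ya_ci_separated(model, "YA")
    dwell = dict(zip(spec.group_labels, spec.dwell_mean_s))
    return {
        "spec": spec,
        "features": features,
        "model": model,
        "mu_jl_by_group": mu_by_group,
        "dwell_by_group": dwell,
        "mu_orders_opposite_to_dwell": _opposite_order(mu_by_group, dwell),
        "ya_ci_separated": separated,
    }


def _opposite_order(mu_by_group, dwell_by_group) -> bool:
    groups = list(mu_by_group.index)
    by_dwell = sorted(groups, key=lambda g: dwell_by_group[g])
    mu = [float(mu_by_group[g]) for g in by_dwell]
    return all(a > b for a, b in zip(mu, mu[1:]))


def _ya_ci_separated(model, ya_label: str) -> bool:
    """LV1 bootstrap CIs of every YA cell disjoint from same-condition cells."""
    cis = model.score_cell_cis_[:, 0, :]
    cells = model.cell_labels_
    for i, (gi, ci) in enumerate(cells):
        if gi != ya_label:
            continue
        for j, (gj, cj) in enumerate(cells):
            if gj == ya_label or cj != ci:
                continue
            lo_i, hi_i = cis[i]
            lo_j, hi_j = cis[j]
            if not (hi_i < lo_j or hi_j < lo_i):
                return False
    return True
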