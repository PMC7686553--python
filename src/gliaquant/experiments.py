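"""End-to-end simulation studies exercising the full pipeline.

Each study generates synthetic fields with known ground truth, runs the
same analysis path a user would (projection, thresholding, skeletonization,
Sholl, statistics) and reports recovery rates.  They are used both by the
test suite and by the reproduction script.

Problem sizes are chosen so each study completes in minutes on one CPU:
cohorts of 40 Sholl centres per group for the zone study, ~32 neuron
centres per field for the attraction study, 20 replicates, and 500
replicates for the ANOVA null calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core import CortexLayout
from .imgsim import SimParams, generate_cortex_stack
from .interaction3d import NeuronCenterSet, neuron_sholl_2d
from .microglia import binarize, skeletonize, sholl_2d, zone_statistics
from .nuclei import ThresholdPair, classify_activation, detect_nuclei, project_stack
from .stats_report import compare_two, two_way_anova_bonferroni

__all__ = [
    "classification_recovery_study",
    "zone_effect_study",
    "attraction_study",
    "anova_null_study",
    "microglia_field_layout",
    "nucleus_field_layout",
]


def _seed_of(base_seed: int, k: int) -> int:
    return (int(base_seed) * 100003 + 7919 * k) % (2**31 - 1)


def microglia_field_layout(n_cols: int = 8, n_rows: int = 5) -> CortexLayout:
    """A field sized for an n_cols x n_rows soma grid at ~65 um spacing,
    with a 40 um margin so full 40 um Sholl circles stay in bounds."""
    spacing = 65.0
    fx = n_cols * spacing + 40.0
    fy = n_rows * spacing + 40.0
    return CortexLayout(layer_widths=[("V", fx)], field_size_um=(fx, fy, 10.0))


def nucleus_field_layout() -> CortexLayout:
    """Full cortical layer sequence (I, II/III, V, VI) over a 300 um strip."""
    from .core import default_mpfc_layout

    return default_mpfc_layout(field_y_um=300.0)


# ---------------------------------------------------------------------------
# classification recovery


@dataclass
class ClassificationRecovery:
    noise_free_exact: bool
    per_seed_exact: list[bool]
    noisy_count_error_pct: float
    n_seeds: int


def _run_classification(params: SimParams, layout: CortexLayout):
    stack, truth = generate_cortex_stack(params, layout, nz=1)
    img = stack.channel("cfos")
    detected = detect_nuclei(img, stack.pixel_size_um, min_area_um2=20.0)
    classified = classify_activation(detected, ThresholdPair(200.0, 400.0))
    got = {
        "cfos_plus": sum(1 for n in classified if n.activation_class == "cfos_plus"),
        "cfos_plusplus": sum(
            1 for n in classified if n.activation_class == "cfos_plusplus"
        ),
    }
    want = {
        c: sum(1 for t in truth.nuclei if t.activation_class == c)
        for c in ("cfos_plus", "cfos_plusplus")
    }
    return got, want


def classification_recovery_study(
    n_seeds: int = 20, seed: int = 0, noise_sd: float | None = None
) -> ClassificationRecovery:
    """Detect and classify generated nuclei, noise-free and at the
    generator's stated noise level, against ground truth."""
    layout = nucleus_field_layout()
    exact = []
    errors = []
    for k in range(n_seeds):
        base = SimParams(seed=_seed_of(seed, k), noise_sd=0.0)
        got, want = _run_classification(base, layout)
        exact.append(got == want)
        noisy = dataclasses.replace(
            base, noise_sd=SimParams().noise_sd if noise_sd is None else noise_sd
        )
        got_n, want_n = _run_classification(noisy, layout)
        total_want = sum(want_n.values())
        total_got = sum(got_n.values())
        errors.append(100.0 * abs(total_got - total_want) / total_want)
    return ClassificationRecovery(
        noise_free_exact=all(exact),
        per_seed_exact=exact,
        noisy_count_error_pct=float(np.mean(errors)),
        n_seeds=n_seeds,
    )


# ---------------------------------------------------------------------------
# zone-effect recovery (inter-cellular branch density)


@dataclass
class ZoneEffectResult:
    detected: list[bool]  # 20-40 um zone significant
    false_pos: list[bool]  # 0-20 um zone significant
    n_replicates: int

    @property
    def detection_rate(self) -> float:
        return float(np.mean(self.detected))

    @property
    def false_positive_rate(self) -> float:
        return float(np.mean(self.false_pos))


def _cohort_profiles(params: SimParams, layout: CortexLayout, n_centers: int):
    stack, truth = generate_cortex_stack(params, layout, nz=1)
    mask, _ = binarize(stack.channel("microglia"))
    skel = skeletonize(mask, stack.pixel_size_um)
    centers = truth.somata_um[:n_centers]
    return [sholl_2d(skel, tuple(c[:2]), 40.0, 1.0) for c in centers]


def zone_effect_study(
    n_replicates: int = 20,
    density_ratio: float = 1.3,
    n_centers: int = 40,
    seed: int = 0,
    alpha: float = 0.05,
) -> ZoneEffectResult:
    """Two cohorts differing only in inter-cellular branch density.

    Within a replicate both cohorts share every random draw except the
    number of inter-cellular segments (common-random-number pairing), so
    the 0-20 um single-cell zone is a true null while the 20-40 um zone
    carries the density effect.  Detection = Mann-Whitney p < alpha in the
    20-40 um zone; false positive = p < alpha in the 0-20 um zone.
    """
    layout = microglia_field_layout()
    detected, false_pos = [], []
    for k in range(n_replicates):
        s = _seed_of(seed, k)
        base = SimParams(
            nucleus_count={"negative": 0, "cfos_plus": 0, "cfos_plusplus": 0},
            seed=s,
        )
        dense = dataclasses.replace(base, intercell_branch_density=density_ratio)
        profs = {
            "baseline": _cohort_profiles(base, layout, n_centers),
            "dense": _cohort_profiles(dense, layout, n_centers),
        }
        _, tests = zone_statistics(profs)
        p_inner = float(tests.loc[tests["zone_lo_um"] == 0.0, "p"].iloc[0])
        p_outer = float(tests.loc[tests["zone_lo_um"] == 20.0, "p"].iloc[0])
        detected.append(p_outer < alpha)
        false_pos.append(p_inner < alpha)
    return ZoneEffectResult(detected=detected, false_pos=false_pos, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# attraction recovery (branches near activated nuclei)


@dataclass
class AttractionResult:
    correct_direction: list[bool]  # significant AND activated > inactive
    n_replicates: int

    @property
    def rate(self) -> float:
        return float(np.mean(self.correct_direction))


def attraction_study(
    n_replicates: int = 20,
    attraction: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    small_radius_um: float = 8.0,
) -> AttractionResult:
    """Neuron-centred profiles with (or without) preferential branch
    placement near activated nuclei.

    Each replicate renders one field with activated (c-Fos+) and inactive
    nuclei plus the microglial network; per-centre mean skeleton crossings
    over radii <= ``small_radius_um`` are compared between statuses.  A
    replicate scores positive when the Mann-Whitney p falls below alpha
    *and* the activated group mean is the larger - so with
    ``attraction=0`` the positive rate estimates the false-positive rate.
    """
    layout = microglia_field_layout(n_cols=6, n_rows=4)
    results = []
    for k in range(n_replicates):
        params = SimParams(
            nucleus_count={"negative": 16, "cfos_plus": 8, "cfos_plusplus": 8},
            activation_attraction=attraction,
            seed=_seed_of(seed, k),
        )
        stack, truth = generate_cortex_stack(params, layout, nz=1)
        mask, _ = binarize(stack.channel("microglia"))
        skel = skeletonize(mask, stack.pixel_size_um)
        centers = np.array([t.center_um[:2] for t in truth.nuclei])
        status = [
            "inactive" if t.activation_class == "negative" else "activated"
            for t in truth.nuclei
        ]
        groups = neuron_sholl_2d(
            skel, NeuronCenterSet(centers, status), r_max_um=small_radius_um, dr_um=1.0
        )
        mean_act = np.array([p.crossings.mean() for p in groups["activated"]])
        mean_ina = np.array([p.crossings.mean() for p in groups["inactive"]])
        _, pval = compare_two(mean_act, mean_ina, test="mannwhitney")
        results.append(pval < alpha and mean_act.mean() > mean_ina.mean())
    return AttractionResult(correct_direction=results, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# statistical null calibration


def anova_null_study(
    n_replicates: int = 500, n_per_cell: int = 5, seed: int = 0, alpha: float = 0.05
) -> float:
    """Family-wise error of the Bonferroni-adjusted pairwise comparisons
    under a fully inert 2x2 design; returns the fraction of replicates
    with any adjusted p below alpha."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    hits = 0
    fa = np.repeat(["g1", "g2"], 2 * n_per_cell)
    fb = np.tile(np.repeat(["l1", "l2"], n_per_cell), 2)
    for _ in range(n_replicates):
        df = pd.DataFrame(
            {"value": rng.normal(size=4 * n_per_cell), "group": fa, "level": fb}
        )
        res = two_way_anova_bonferroni(df)
        if (res.pairwise["p_adjusted"] < alpha).any():
            hits += 1
    return hits / n_replicates
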