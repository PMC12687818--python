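"""Cohort generator: genetics, traits, planted survival, detections,
missingness, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from hybridsurv import simulate
from hybridsurv.simulate import SimBird, SimConfig


def _make_bird(cfg, rng, hybrid_class="F2"):
    bird = SimBird(bird_id="B0", hybrid_class=hybrid_class)
    bird.ancestry_q, bird.heterozygosity_H = simulate.simulate_genotype(
        hybrid_class, cfg.n_loci, rng
    )
    return simulate.simulate_traits(bird, cfg, rng)


@pytest.mark.parametrize(
    "hclass, q, h",
    [("F1", 0.5, 1.0), ("inland_parental", 1.0, 0.0), ("coastal_parental", 0.0, 0.0)],
)
def test_genotype_degenerate_classes_exact(hclass, q, h, rng):
    for _ in range(5):
        got_q, got_h = simulate.simulate_genotype(hclass, 1495, rng)
        assert (got_q, got_h) == (q, h)


def test_genotype_backcross_expectation(rng):
    # per-locus mixture {inland-hom 1/2, het 1/2} -> E[q]=0.75, E[H]=0.5
    qs, hs = zip(*(simulate.simulate_genotype("backcross_inland", 1495, rng) for _ in range(1000)))
    assert abs(np.mean(qs) - 0.75) < 0.02
    assert abs(np.mean(hs) - 0.5) < 0.02


def test_genotype_unknown_class(rng):
    with pytest.raises(ValueError, match="unknown hybrid class"):
        simulate.simulate_genotype("mule", 10, rng)


def test_triangle_constraint_holds_cohort(small_cohort):
    _, _, traits, _ = small_cohort
    q = traits["ancestry"].to_numpy()
    h = traits["heterozygosity"].to_numpy()
    assert np.all(h <= 2 * np.minimum(q, 1 - q) + 1e-9)


def test_morphology_correlation_target(rng):
    cfg = SimConfig(n_birds=1, morphology_correlation={("wing_chord", "p8"): 0.9})
    birds = [_make_bird(cfg, rng) for _ in range(500)]
    wing = [b.morphology["wing_chord"] for b in birds]
    p8 = [b.morphology["p8"] for b in birds]
    r = np.corrcoef(wing, p8)[0, 1]
    assert 0.8 <= r <= 0.97


def test_morphology_correlation_not_psd(rng):
    bad = {("wing_chord", "p7"): 0.95, ("wing_chord", "p8"): 0.95, ("p7", "p8"): -0.9}
    cfg = SimConfig(n_birds=1, morphology_correlation=bad)
    bird = SimBird(bird_id="B0", hybrid_class="F1", ancestry_q=0.5, heterozygosity_H=1.0)
    with pytest.raises(ValueError, match="positive semi-definite"):
        simulate.simulate_traits(bird, cfg, rng)


def _circular_mean_deg(bearings):
    rad = np.radians(bearings)
    return math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))) % 360.0


@pytest.mark.parametrize("hclass, east", [("inland_parental", True), ("coastal_parental", False)])
def test_bearing_rotates_with_ancestry(hclass, east, rng):
    cfg = SimConfig(n_birds=1)
    bearings = [_make_bird(cfg, rng, hclass).fall_bearing for _ in range(400)]
    mean = _circular_mean_deg(bearings)
    # compass: east of due south means < 180 deg, west of south > 180 deg
    assert (mean < 180.0) == east


def test_bearing_uniform_at_zero_concentration(rng):
    cfg = SimConfig(n_birds=1, bearing_kappa=0.0)
    bearings = np.array([_make_bird(cfg, rng).fall_bearing for _ in range(1000)])
    assert np.all((bearings >= 0) & (bearings < 360))
    # Rayleigh test for circular uniformity must not reject at alpha = 0.01
    rad = np.radians(bearings)
    n = len(rad)
    R = np.hypot(np.mean(np.cos(rad)), np.mean(np.sin(rad)))
    z = n * R**2
    p_value = math.exp(-z) * (1 + (2 * z - z**2) / (4 * n))
    assert p_value > 0.01


def test_planted_survival_base_rate(rng):
    # with every coefficient zero the survivor fraction equals the base rate
    cfg = SimConfig(n_birds=1, survival_coefficients={}, base_survival_rate=0.309)
    n = 10_000
    survived = 0
    for _ in range(n):
        bird = _make_bird(cfg, rng)
        survived += simulate.plant_survival(bird, cfg, rng)
    assert abs(survived / n - 0.309) < 0.015


def test_planted_condition_effect_monotone(rng):
    cfg = SimConfig(n_birds=1, survival_coefficients={"condition": 2.0})
    birds = [_make_bird(cfg, rng) for _ in range(4000)]
    surv = np.array([simulate.plant_survival(b, cfg, rng) for b in birds])
    cond = np.array([b.body_condition for b in birds])
    edges = np.quantile(cond, [0, 0.25, 0.5, 0.75, 1.0])
    rates = [surv[(cond >= lo) & (cond <= hi)].mean() for lo, hi in zip(edges, edges[1:])]
    assert all(a < b for a, b in zip(rates, rates[1:]))


def test_planted_intercept_saturation(rng):
    cfg = SimConfig(n_birds=1, survival_coefficients={"intercept": 50.0})
    assert all(simulate.plant_survival(_make_bird(cfg, rng), cfg, rng) for _ in range(100))


def test_planted_unknown_term(rng):
    cfg = SimConfig(n_birds=1, survival_coefficients={"wingspan": 1.0})
    with pytest.raises(ValueError, match="unknown survival-effect term"):
        simulate.plant_survival(_make_bird(cfg, rng), cfg, rng)


def test_cohort_imbalance_matches_base_rate():
    cfg = SimConfig(n_birds=600, seed=3)
    _, traits, _ = simulate.generate_cohort(cfg)
    rate = traits["survived_true"].mean()
    half_width = 2.576 * math.sqrt(0.309 * 0.691 / 600)  # binomial 99% bounds
    assert abs(rate - 0.309) < half_width


@pytest.mark.parametrize("frac, lo, hi", [(0.28, 250, 310), (0.0, 0, 0), (1.0, 1000, 1000)])
def test_missingness_fraction(frac, lo, hi, rng):
    cfg = SimConfig(n_birds=1, missing_frac_behaviour=frac, missing_frac_other=0.0)
    birds = [_make_bird(cfg, rng) for _ in range(1000)]
    simulate.apply_missingness(birds, cfg, rng)
    n_missing = sum(math.isnan(b.fall_bearing) for b in birds)
    assert lo <= n_missing <= hi
    # shared mask: timing missing exactly where bearing is
    assert all(math.isnan(b.fall_timing) == math.isnan(b.fall_bearing) for b in birds)


def test_detections_certain_detection(rng):
    cfg = SimConfig(n_birds=1, detection_prob=1.0)
    bird = _make_bird(cfg, rng)
    bird.survived_true = True
    events = pd.DataFrame(simulate.simulate_detections(bird, cfg, rng))
    occ = (events["days_since_tag"] // 10).astype(int)
    assert set(occ[occ < 30]) == set(range(30))  # every in-window occasion
    assert (events["days_since_tag"] > 240).any()


def test_detections_stop_at_death(rng):
    cfg = SimConfig(n_birds=1, detection_prob=1.0)
    bird = _make_bird(cfg, rng)
    bird.survived_true = False
    bird.death_occasion = 3
    events = pd.DataFrame(simulate.simulate_detections(bird, cfg, rng))
    assert events["days_since_tag"].max() < 40  # nothing beyond occasion 3


def test_detections_invalid_probability(rng):
    cfg = SimConfig(n_birds=1)
    cfg.detection_prob = 1.4  # bypass construction-time validation
    bird = _make_bird(SimConfig(n_birds=1), rng)
    bird.survived_true = True
    with pytest.raises(ValueError, match="detection_prob"):
        simulate.simulate_detections(bird, cfg, rng)


def test_survivor_spring_detection_coverage():
    cfg = SimConfig(n_birds=1200, seed=9, detection_prob=0.8)
    _, traits, det = simulate.generate_cohort(cfg)
    survivors = traits.loc[traits["survived_true"] == 1, "bird_id"]
    spring = det[det["days_since_tag"] > 240].groupby("bird_id").size()
    frac = np.mean([bid in spring.index for bid in survivors])
    assert frac >= 0.99  # 1 - (1-p)^k over the spring occasions


def test_cohort_determinism():
    a = simulate.generate_cohort(SimConfig(n_birds=60, seed=13))
    b = simulate.generate_cohort(SimConfig(n_birds=60, seed=13))
    c = simulate.generate_cohort(SimConfig(n_birds=60, seed=14))
    pd.testing.assert_frame_equal(a[1], b[1])
    pd.testing.assert_frame_equal(a[2], b[2])
    assert not a[1].equals(c[1])


def test_planted_effect_recovered_by_classifier():
    """A single strong planted effect should top the downstream importance
    ranking in >= 9/10 seeded replicates."""
    from hybridsurv import features, model

    hits = 0
    for seed in range(10):
        cfg = SimConfig(
            n_birds=300, seed=100 + seed,
            survival_coefficients={"condition": 2.5, "intercept": -0.2},
        )
        _, traits, det = simulate.generate_cohort(cfg)
        candidates = features.build_feature_matrix(traits, det)
        prep = features.prepare_features(candidates, traits["survived_true"], seed=seed)
        forest = model.train_forest(
            prep.X_train.to_numpy(), prep.y_train,
            model.ForestConfig(n_estimators=100, seed=seed),
        )
        top = prep.feature_names[int(np.argmax(forest.feature_importances_))]
        hits += top == "condition"
    assert hits >= 9
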