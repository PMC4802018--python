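"""Initialization, coarse-to-fine search, frame registration, best frame."""

import itertools

import numpy as np
import pytest

import atriareg as ar
from atriareg.projection import back_project_ray
from atriareg.registration import (
    FrameRegistration,
    SearchConfig,
    coarse_to_fine_search,
    initialize,
    select_best_frame,
)
from atriareg.similarity import rho_combined, SimilarityConfig


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def test_initialize_centered_geometry_hits_isocenter(centered_geometry):
    """Centered principal points: both image-center rays pass through the
    iso-center, so the triangulation returns it."""
    t = initialize(centered_geometry).t
    assert np.allclose(t, 0.0, atol=1e-6)


def test_initialize_offset_geometry_matches_ray_triangulation(geometry):
    """Skew rays: the result is the closest-approach midpoint, equidistant
    from both back-projected rays."""
    init = initialize(geometry).t

    def dist_to_ray(p, origin, direction):
        w = p - origin
        return np.linalg.norm(w - (w @ direction) * direction)

    rows, cols = geometry.image_shape
    center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    o1, d1 = back_project_ray(geometry.P_A, center)
    o2, d2 = back_project_ray(geometry.P_B, center)
    assert dist_to_ray(init, o1, d1) == pytest.approx(dist_to_ray(init, o2, d2), abs=1e-9)
    # and it is at least 30 mm from the iso-center where the phantom sits
    assert np.linalg.norm(init) >= 30.0


# ---------------------------------------------------------------------------
# coarse-to-fine search
# ---------------------------------------------------------------------------


def _quadratic(t0):
    t0 = np.asarray(t0, dtype=float)

    def objective(T):
        return -float(np.sum((T.t - t0) ** 2))

    return objective


def test_search_finds_on_lattice_optimum_exactly():
    cfg = SearchConfig(range_mm=16, level0_step_mm=8, min_step_mm=1)
    t0 = np.array([8.0, -8.0, 0.0])  # on the level-0 lattice
    T, val = coarse_to_fine_search(_quadratic(t0), ar.RigidTransform((0, 0, 0)), cfg)
    assert np.array_equal(T.t, t0)
    assert val == 0.0


def test_search_reaches_off_lattice_optimum_within_min_step():
    cfg = SearchConfig(range_mm=16, level0_step_mm=8, min_step_mm=1)
    t0 = np.array([3.3, -5.7, 6.1])
    T, _ = coarse_to_fine_search(_quadratic(t0), ar.RigidTransform((0, 0, 0)), cfg)
    assert np.linalg.norm(T.t - t0, ord=np.inf) <= 1.0


def test_search_dominates_its_own_coarse_level():
    """Refinement only adds evaluations, so the result is at least as good
    as exhaustive search at the level-0 spacing."""
    cfg = SearchConfig(range_mm=16, level0_step_mm=8, min_step_mm=1)
    rng = np.random.default_rng(5)
    for _ in range(3):
        t0 = rng.uniform(-12, 12, 3)
        _, val = coarse_to_fine_search(_quadratic(t0), ar.RigidTransform((0, 0, 0)), cfg)
        coarse_cfg = SearchConfig(range_mm=16, level0_step_mm=8, min_step_mm=4.1)
        _, coarse_val = coarse_to_fine_search(
            _quadratic(t0), ar.RigidTransform((0, 0, 0)), coarse_cfg
        )
        assert val >= coarse_val


def test_search_discards_nonfinite_cells():
    def objective(T):
        if T.t[0] < 0:
            return np.nan
        return -float(np.sum(T.t**2))

    cfg = SearchConfig(range_mm=8, level0_step_mm=4, min_step_mm=1)
    T, val = coarse_to_fine_search(objective, ar.RigidTransform((0, 0, 0)), cfg)
    assert np.isfinite(val)
    assert np.allclose(T.t, 0.0)


def test_search_is_deterministic():
    rng = np.random.default_rng(6)
    noise = {}

    def objective(T):
        key = tuple(T.t)
        if key not in noise:
            noise[key] = rng.normal()
        return noise[key]

    cfg = SearchConfig(range_mm=8, level0_step_mm=4, min_step_mm=1)
    T1, v1 = coarse_to_fine_search(objective, ar.RigidTransform((0, 0, 0)), cfg)
    T2, v2 = coarse_to_fine_search(objective, ar.RigidTransform((0, 0, 0)), cfg)
    assert np.array_equal(T1.t, T2.t) and v1 == v2


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(range_mm=4, level0_step_mm=8)
    with pytest.raises(ValueError):
        SearchConfig(keep_top_k=0)


# ---------------------------------------------------------------------------
# frame registration
# ---------------------------------------------------------------------------


def test_register_frame_recovers_truth(fullfill, model):
    """Quick recovery check from a near init (full capture-range recovery is
    exercised by the acceptance suite)."""
    seq, truth, i = fullfill
    cfg = SearchConfig(
        init_mode="explicit", explicit_init=(0.0, 0.0, 0.0),
        range_mm=16, level0_step_mm=8, min_step_mm=1,
    )
    reg = ar.register_frame(seq, i, model, config=cfg, measure="shad_thr")
    assert np.linalg.norm(reg.T_prime.t - truth.translations[i]) <= 2.0
    assert reg.measure_name == "shad_thr"


def test_register_frame_rho_matches_measure_at_optimum(fullfill, model, fullfill_preps):
    seq, truth, i = fullfill
    cfg = SearchConfig(
        init_mode="explicit", explicit_init=(0.0, 0.0, 0.0),
        range_mm=8, level0_step_mm=4, min_step_mm=2,
    )
    reg = ar.register_frame(seq, i, model, config=cfg, measure="shad_thr")
    prepA, prepB = fullfill_preps
    direct = rho_combined(
        prepA, prepB, model, seq.geometry, reg.T_prime, SimilarityConfig("shad_thr")
    )
    assert reg.rho_value == pytest.approx(direct, abs=1e-12)


def test_register_uncontrasted_frame_raises(fullfill, model):
    seq, _, _ = fullfill
    unc = int(np.flatnonzero(~seq.contrasted)[0])
    with pytest.raises(ValueError, match="uncontrasted"):
        ar.register_frame(seq, unc, model)


# ---------------------------------------------------------------------------
# best-frame selection
# ---------------------------------------------------------------------------


def _fake_regs(rhos):
    return [
        FrameRegistration(i, ar.RigidTransform((float(i), 0, 0)), float(r), "m")
        for i, r in enumerate(rhos)
    ]


def test_single_frame_selected():
    assert select_best_frame(_fake_regs([0.4])) == 0


def test_argmax_and_tie_breaking():
    assert select_best_frame(_fake_regs([0.1, 0.5, 0.3])) == 1
    assert select_best_frame(_fake_regs([0.2, 0.7, 0.7])) == 1  # lowest index wins
    assert select_best_frame(_fake_regs([0.1, 0.2, 0.9])) == 2


def test_empty_list_raises():
    with pytest.raises(ValueError, match="no registrations"):
        select_best_frame([])


def test_cross_selection_matches_exhaustive_ranking(model, spec, geometry):
    """Cross-selection keeps each frame's CADE pose but ranks frames by the
    thresholded-shadow measure; the winner equals the exhaustive ranking
    oracle and is the most-opacified frame."""
    scn = ar.vein_injection_scenario(noise_sd=4.0, artifacts=False)
    seq, _ = ar.simulate_sequence(model, scn, geometry, seed=9, pv_specs=spec.pv_specs)
    frames = [i for i in range(seq.n_frames) if seq.contrasted[i]]
    cfg = SearchConfig(
        init_mode="explicit", explicit_init=(0.0, 0.0, 0.0),
        range_mm=16, level0_step_mm=8, min_step_mm=2,
    )
    regs = ar.register_sequence(seq, model, config=cfg, measure="cade", frame_indices=frames)
    pick = select_best_frame(regs, selector_measure="shad_thr", sequence=seq, model=model)

    # oracle: evaluate the selector at every frame's pose, rank exhaustively
    sim = SimilarityConfig("shad_thr")
    scores = []
    for r in regs:
        pA, pB = ar.preprocess_frame(seq, r.frame_index)
        scores.append(rho_combined(pA, pB, model, seq.geometry, r.T_prime, sim))
    assert pick == regs[int(np.argmax(scores))].frame_index

    # the thresholded-shadow ranking favors the most-opacified frame
    areas = [ar.preprocess_frame(seq, i)[0].I_thr.sum() for i in frames]
    assert pick == frames[int(np.argmax(areas))]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_search_dominates_exhaustive_on_phantom_measures(seed, geometry):
    """On a 10 mm box around truth, coarse-to-fine search down to 1 mm finds
    at least the best value of exhaustive 2 mm-grid search, for every
    similarity measure, on seeded phantoms."""
    spec = ar.PhantomSpec(seed=seed)
    model = ar.build_phantom(spec)
    scn = ar.vein_injection_scenario(noise_sd=4.0, artifacts=False, vein=seed % 4)
    seq, truth = ar.simulate_sequence(model, scn, geometry, seed=seed, pv_specs=spec.pv_specs)
    i = int(np.argmax(scn.fill_fractions))
    prepA, prepB = ar.preprocess_frame(seq, i)
    t0 = truth.translations[i]
    for measure in ar.MEASURES:
        sim = SimilarityConfig(measure)

        def objective(T, sim=sim):
            return rho_combined(prepA, prepB, model, seq.geometry, T, sim)

        exhaustive = max(
            objective(ar.RigidTransform(t0 + np.array(off)))
            for off in itertools.product((-4.0, -2.0, 0.0, 2.0, 4.0), repeat=3)
        )
        cfg = SearchConfig(
            init_mode="explicit", explicit_init=tuple(t0),
            range_mm=5.0, level0_step_mm=2.0, min_step_mm=1.0,
        )
        _, val = coarse_to_fine_search(objective, ar.RigidTransform(t0), cfg)
        assert val >= exhaustive - 1e-12, measure
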