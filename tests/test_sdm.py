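"""Variable screening, background sampling and the hinge-maxent estimator."""
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from refugia.grid import GridSpec, RasterStack
from refugia import synthetic as syn
from refugia.sdm import (
    BackgroundSet,
    HingeBasis,
    MaxentSDM,
    build_background,
    fit_entropy_model,
    project_model,
    screen_variables,
)


@pytest.fixture(scope="module")
def stack():
    cur, _ = syn.generate_climate_stack(GridSpec(30, 30), n_layers=4, seed=5)
    return cur


@pytest.fixture(scope="module")
def bg_cells(stack):
    return np.argwhere(stack.finite_mask())[::3]


class TestScreening:
    def test_duplicated_layer_keeps_one(self, stack, bg_cells):
        dup = RasterStack(
            grid=stack.grid,
            layers={**stack.layers, "copy": stack.layers["bio1"].copy()},
        )
        kept = screen_variables(dup, bg_cells, priority=["bio1", "copy", "bio2", "bio3", "bio4"])
        assert "bio1" in kept and "copy" not in kept

    def test_independent_layers_all_retained(self, stack, bg_cells):
        kept = screen_variables(stack, bg_cells)
        assert kept == stack.layer_names

    def test_retained_set_always_below_threshold(self, stack, bg_cells):
        for order in (stack.layer_names, stack.layer_names[::-1]):
            kept = screen_variables(stack, bg_cells, threshold=0.7, priority=order)
            vals = {n: stack.layers[n][bg_cells[:, 0], bg_cells[:, 1]] for n in kept}
            for i, a in enumerate(kept):
                for b in kept[i + 1 :]:
                    assert abs(np.corrcoef(vals[a], vals[b])[0, 1]) < 0.7

    def test_constant_layer_dropped_with_warning(self, stack, bg_cells):
        with_const = RasterStack(
            grid=stack.grid, layers={**stack.layers, "flat": np.zeros(stack.grid.shape)}
        )
        with pytest.warns(UserWarning, match="flat"):
            kept = screen_variables(with_const, bg_cells)
        assert "flat" not in kept


class TestBackground:
    def test_buffer_respects_haversine_distance(self, stack):
        loc = pd.DataFrame({"lon": [stack.grid.cell_center(15, 15)[0]],
                            "lat": [stack.grid.cell_center(15, 15)[1]]})
        bg = build_background(loc, stack, buffer_km=60.0, n_background=10_000, seed=0)

        def haversine_km(lon1, lat1, lon2, lat2):
            r = 6371.0088
            p1, p2 = np.radians(lat1), np.radians(lat2)
            dl = np.radians(lon2 - lon1)
            dp = p2 - p1
            a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
            return 2 * r * np.arcsin(np.sqrt(a))

        for (lon, lat) in bg.coords:
            # equirectangular vs great-circle differ well below 1% here
            assert haversine_km(loc.lon[0], loc.lat[0], lon, lat) <= 60.0 * 1.01

    def test_full_buffer_covers_grid(self, stack):
        lons, lats = stack.grid.center_mesh()
        loc = pd.DataFrame({"lon": lons.ravel()[::7], "lat": lats.ravel()[::7]})
        bg = build_background(loc, stack, buffer_km=500.0, n_background=10_000, seed=0)
        assert bg.buffer_mask.all()

    def test_deterministic_and_warns_when_short(self, stack):
        loc = pd.DataFrame({"lon": [stack.grid.cell_center(5, 5)[0]],
                            "lat": [stack.grid.cell_center(5, 5)[1]]})
        with pytest.warns(UserWarning, match="available"):
            a = build_background(loc, stack, buffer_km=30, n_background=10_000, seed=1)
        with pytest.warns(UserWarning):
            b = build_background(loc, stack, buffer_km=30, n_background=10_000, seed=2)
        assert np.array_equal(a.cells, b.cells)  # all available cells, order fixed


class TestHingeBasis:
    @pytest.fixture(scope="class")
    def basis(self):
        X = np.random.default_rng(2).normal(size=(200, 1))
        return HingeBasis(X, ["v"], n_knots=5), X

    def test_value_at_knot_is_zero_forward(self, basis):
        b, X = basis
        for f, (j, knot, direction) in enumerate(b.features):
            if direction == "forward":
                assert b.transform(np.array([[knot]]))[0, f] == 0.0

    def test_background_max_saturates_forward_hinges(self, basis):
        b, X = basis
        at_max = b.transform(np.array([[X.max()]]))
        for f, (_, _, direction) in enumerate(b.features):
            if direction == "forward":
                assert at_max[0, f] == pytest.approx(1.0)

    def test_clamping_beyond_range(self, basis):
        b, X = basis
        assert np.allclose(
            b.transform(np.array([[X.max() + 100]])), b.transform(np.array([[X.max()]]))
        )

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            HingeBasis(np.ones((10, 1)), ["v"])


def separable_toy():
    """Presence concentrated where the single variable is high."""
    rng = np.random.default_rng(0)
    bg = rng.uniform(0, 1, size=(100, 1))
    pres = rng.uniform(0.85, 1.0, size=(25, 1))
    X = np.vstack([pres, bg])
    y = np.r_[np.ones(25), np.zeros(100)]
    return X, y


class TestMaxent:
    def test_separable_signal_learned(self):
        X, y = separable_toy()
        m = MaxentSDM(n_knots=4).fit(X, y)
        raw = m.predict_raw(X)
        assert raw[y == 1].mean() > raw[y == 0].mean()
        # some forward hinge weight must be positive
        fwd = [w for w, (_, _, d) in zip(m.weights_, m.basis_.features) if d == "forward"]
        assert max(fwd) > 0

    def test_full_shrinkage_gives_uniform_distribution(self):
        X, y = separable_toy()
        m = MaxentSDM(beta=1e6, n_knots=4).fit(X, y)
        assert np.allclose(m.weights_, 0.0)
        raw_bg = m.predict_raw(X[y == 0])
        assert np.allclose(raw_bg, 1.0 / (y == 0).sum())

    def test_raw_normalizes_over_background(self):
        X, y = separable_toy()
        m = MaxentSDM(n_knots=6).fit(X, y)
        assert m.predict_raw(X[y == 0]).sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_perturbation_improves_penalized_objective(self):
        X, y = separable_toy()
        m = MaxentSDM(n_knots=4).fit(X, y)
        base = m.penalized_objective(m.weights_, X, y)
        rng = np.random.default_rng(1)
        for scale in (1e-3, 1e-2, 0.1):
            for _ in range(20):
                w = m.weights_ + rng.normal(scale=scale, size=m.weights_.shape)
                assert m.penalized_objective(w, X, y) <= base + 1e-7

    def test_brute_force_grid_oracle_tiny_problem(self):
        # 12 background cells, one variable, one knot per direction = 2 features
        x = np.linspace(0, 1, 12)[:, None]
        pres = np.array([[0.8], [0.85], [0.9], [0.95], [1.0]])
        X = np.vstack([pres, x])
        y = np.r_[np.ones(5), np.zeros(12)]
        m = MaxentSDM(n_knots=1).fit(X, y)
        assert len(m.basis_) == 2
        grid = np.arange(-4, 4.0001, 0.05)
        best = -np.inf
        for w1 in grid:
            for w2 in grid:
                best = max(best, m.penalized_objective(np.array([w1, w2]), X, y))
        assert m.penalized_objective(m.weights_, X, y) >= best - 1e-4

    def test_training_auc_beats_single_variables_on_separable_niche(self):
        from refugia.significance import auc

        rng = np.random.default_rng(4)
        bg = rng.uniform(-2, 2, size=(150, 2))
        pres = rng.normal(loc=[1.0, -1.0], scale=0.15, size=(30, 2))
        X = np.vstack([pres, bg])
        y = np.r_[np.ones(30), np.zeros(150)]
        m = MaxentSDM(n_knots=6).fit(X, y)
        model_auc = auc(m.predict_raw(pres), m.predict_raw(bg))
        for j in range(2):
            for sign in (1, -1):
                assert model_auc >= auc(sign * pres[:, j], sign * bg[:, j])

    def test_sklearn_protocol_and_validation(self):
        m = MaxentSDM(beta=2.0, n_knots=3)
        assert clone(m).get_params()["beta"] == 2.0
        with pytest.raises(ValueError, match="presence"):
            MaxentSDM().fit(np.zeros((6, 1)), np.r_[np.ones(2), np.zeros(4)])


@pytest.fixture(scope="module")
def fitted():
    cur, gla = syn.generate_climate_stack(
        GridSpec(40, 40), n_layers=3,
        gradient_weight=[1.5, 0, 0], glacial_shift=[-1.0, 0, 0], seed=8,
    )
    suit = np.exp(-((cur.layers["bio1"] - 0.8) ** 2) / (2 * 0.6**2))
    occ = syn.sample_occurrences(suit, cur.grid, 60, seed=9)
    mask = cur.finite_mask()
    cells = np.argwhere(mask)
    rng = np.random.default_rng(1)
    bcells = cells[rng.choice(len(cells), 200, replace=False)]
    bg = BackgroundSet(
        cells=bcells, coords=np.zeros((200, 2)),
        X=cur.values_at_cells(bcells, cur.layer_names),
        layer_names=cur.layer_names, buffer_km=0, buffer_mask=mask,
    )
    pres_cells = np.unique(occ[["row", "col"]].to_numpy(), axis=0)
    presX = cur.values_at_cells(pres_cells, cur.layer_names)
    model = fit_entropy_model(presX, bg, n_knots=4)
    return model, cur, gla, bg, suit

class TestProjection:
    def test_training_projection_sums_to_one_over_background(self, fitted):
        model, cur, _, bg, _ = fitted
        raw, _ = project_model(model, cur)
        assert raw[bg.cells[:, 0], bg.cells[:, 1]].sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_weight_model_projects_constant(self, fitted):
        model, cur, _, bg, _ = fitted
        flat = fit_entropy_model(model_presX := cur.values_at_cells(bg.cells[:10]), bg, beta=1e6, n_knots=4)
        _, logistic = project_model(flat, cur)
        vals = logistic[np.isfinite(logistic)]
        assert np.allclose(vals, vals[0])

    def test_glacial_projection_equals_manual_clamp(self, fitted):
        model, cur, gla, _, _ = fitted
        raw_gla, _ = project_model(model, gla)
        clamped_layers = {
            n: np.clip(
                gla.layers[n],
                model.basis_.vmin[model.basis_.layer_names.index(n)],
                model.basis_.vmax[model.basis_.layer_names.index(n)],
            )
            for n in gla.layer_names
        }
        raw_manual, _ = project_model(model, RasterStack(grid=gla.grid, layers=clamped_layers))
        assert np.allclose(raw_gla, raw_manual, equal_nan=True)

    def test_missing_layer_rejected(self, fitted):
        model, cur, _, _, _ = fitted
        partial = RasterStack(grid=cur.grid, layers={"bio1": cur.layers["bio1"]})
        with pytest.raises(ValueError, match="bio2"):
            project_model(model, partial)

    def test_true_range_scores_higher(self, fitted):
        model, cur, _, _, suit = fitted
        _, logistic = project_model(model, cur)
        inside = suit >= 0.5
        assert np.median(logistic[inside]) > np.median(logistic[~inside])
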