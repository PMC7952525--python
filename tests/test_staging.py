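import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ductus.errors import InvalidInputError, MissingMeasurementError, SchemeValidationError
from ductus.hemodynamics import EchoExam
from ductus.staging import (
    builtin_scheme_path,
    compute_score,
    load_scheme,
    model5_scheme,
    scheme_to_config,
    stage_component,
)


def reference_stage(td, ratio, lpa, direction):
    """Independent re-reading of the staging table as literal conditionals."""

    def duct_diameter(v):
        if v == 0:
            return 0
        if v < 1.5:
            return 1
        if v <= 3:
            return 2
        return 3

    def vmax_vmin(v):
        if v == 0:
            return 0
        if v < 1.5:
            return 1
        if v <= 2:
            return 2
        return 3

    def lpa_flow(v):
        if v == 0:
            return 0
        if v < 30:
            return 1
        if v <= 50:
            return 2
        return 3

    return duct_diameter(td) + vmax_vmin(ratio) + lpa_flow(lpa) + {
        "forward": 0,
        "absent": 1,
        "reverse": 2,
    }[direction]


class TestBuiltinScheme:
    def test_metadata(self):
        scheme = model5_scheme()
        assert scheme.max_score == 11
        assert scheme.min_score == 0
        assert len(scheme.components) == 4

    @pytest.mark.parametrize(
        "variable, value, expected",
        [
            ("transductal_diameter", 0.0, 0),
            ("transductal_diameter", 1.49, 1),
            ("transductal_diameter", 1.5, 2),  # boundary joins the closed middle bin
            ("transductal_diameter", 3.0, 2),
            ("transductal_diameter", 3.2, 3),
            ("ductal_vmax_vmin_ratio", 1.5, 2),
            ("ductal_vmax_vmin_ratio", 2.0, 2),
            ("ductal_vmax_vmin_ratio", 2.01, 3),
            ("lpa_diastolic_velocity", 29.9, 1),
            ("lpa_diastolic_velocity", 30.0, 2),
            ("lpa_diastolic_velocity", 50.0, 2),
            ("lpa_diastolic_velocity", 51.0, 3),
            ("dao_flow_direction", "forward", 0),
            ("dao_flow_direction", "absent", 1),
            ("dao_flow_direction", "reverse", 2),
        ],
    )
    def test_component_staging(self, variable, value, expected):
        scheme = model5_scheme()
        assert stage_component(value, scheme.component(variable)) == expected

    def test_invalid_values(self):
        comp = model5_scheme().component("transductal_diameter")
        with pytest.raises(InvalidInputError):
            stage_component(-0.1, comp)
        with pytest.raises(InvalidInputError):
            stage_component("up", model5_scheme().component("dao_flow_direction"))


class TestComputeScore:
    @pytest.mark.parametrize(
        "td, ratio, lpa, direction, total",
        [
            (3.5, 2.5, 60, "reverse", 11),  # most severe category everywhere
            (0.0, 0.0, 0.0, "forward", 0),  # closed duct
            (2.0, 1.6, 35, "reverse", 8),
        ],
    )
    def test_examples(self, td, ratio, lpa, direction, total):
        exam = EchoExam(
            transductal_diameter=td,
            ductal_vmax_vmin_ratio=ratio,
            lpa_diastolic_velocity=lpa,
            dao_flow_direction=direction,
        )
        staged = compute_score(exam)
        assert staged.total == total
        assert staged.total == sum(staged.per_component.values())

    def test_missing_measurement_names_field(self):
        exam = EchoExam(transductal_diameter=2.0, ductal_vmax_vmin_ratio=1.6)
        with pytest.raises(MissingMeasurementError, match="lpa_diastolic_velocity"):
            compute_score(exam)

    def test_grid_against_reference_reading(self):
        """Exhaustive grid crossing every bin boundary matches an independent
        literal re-reading of the staging table."""
        td_grid = [0.0, 0.4, 1.49, 1.5, 2.2, 3.0, 3.01, 6.0]
        ratio_grid = [0.0, 0.7, 1.5, 1.9, 2.0, 2.5]
        lpa_grid = [0.0, 12, 29.9, 30.0, 50.0, 50.1, 75]
        for td in td_grid:
            for ratio in ratio_grid:
                if (td == 0) != (ratio == 0):
                    continue
                for lpa in lpa_grid:
                    for direction in ("forward", "absent", "reverse"):
                        exam = EchoExam(
                            transductal_diameter=td,
                            ductal_vmax_vmin_ratio=ratio,
                            lpa_diastolic_velocity=lpa,
                            dao_flow_direction=direction,
                        )
                        assert compute_score(exam).total == reference_stage(
                            td, ratio, lpa, direction
                        )

    @settings(max_examples=60, deadline=None)
    @given(
        td=st.floats(0.01, 6),
        ratio=st.floats(0.01, 4),
        lpa=st.floats(0.01, 80),
        bump=st.floats(0.01, 3),
        which=st.sampled_from(["transductal_diameter", "ductal_vmax_vmin_ratio", "lpa_diastolic_velocity"]),
    )
    def test_monotone_in_each_measurement(self, td, ratio, lpa, bump, which):
        base = dict(
            transductal_diameter=td,
            ductal_vmax_vmin_ratio=ratio,
            lpa_diastolic_velocity=lpa,
            dao_flow_direction="absent",
        )
        bumped = dict(base)
        bumped[which] += bump
        low = compute_score(EchoExam(**base)).total
        high = compute_score(EchoExam(**bumped)).total
        assert high >= low

    def test_score_bounds_hold_for_100k_random_exams(self):
        rng = np.random.default_rng(2024)
        n = 100_000
        scheme = model5_scheme()
        total = np.zeros(n, dtype=int)
        draws = {
            "transductal_diameter": rng.uniform(0, 8, n),
            "ductal_vmax_vmin_ratio": rng.uniform(0, 5, n),
            "lpa_diastolic_velocity": rng.uniform(0, 120, n),
        }
        for comp in scheme.components:
            if comp.kind == "numeric-binned":
                total += comp.stage_array(draws[comp.variable])
            else:
                total += rng.integers(0, 3, n)  # uniform over the 3 direction scores
        assert total.min() >= 0 and total.max() <= 11


class TestSchemeConfig:
    def test_shipped_config_round_trips_to_builtin(self):
        assert load_scheme(builtin_scheme_path()) == model5_scheme()
        assert load_scheme(scheme_to_config(model5_scheme())) == model5_scheme()

    def test_gap_detected(self):
        config = scheme_to_config(model5_scheme())
        # remove the middle diameter bin: values in [1.5, 3] become unscorable
        config["components"][0]["bins"] = [
            b for b in config["components"][0]["bins"] if b["score"] != 2
        ]
        with pytest.raises(SchemeValidationError, match="transductal_diameter"):
            load_scheme(config)

    def test_overlap_detected(self):
        config = scheme_to_config(model5_scheme())
        config["components"][1]["bins"][2]["low_closed"] = True
        config["components"][1]["bins"][1]["high_closed"] = True  # 1.5 in two bins
        with pytest.raises(SchemeValidationError):
            load_scheme(config)

    def test_max_score_sums_components(self):
        config = {
            "name": "three-component",
            "components": [
                {
                    "variable": v,
                    "kind": "numeric-binned",
                    "bins": [
                        {"low": 0, "high": 0, "low_closed": True, "high_closed": True, "score": 0},
                        {"low": 0, "high": 1, "low_closed": False, "high_closed": True, "score": 1},
                        {"low": 1, "high": None, "low_closed": False, "high_closed": False, "score": s},
                    ],
                }
                for v, s in [("a", 3), ("b", 3), ("c", 2)]
            ],
        }
        assert load_scheme(config).max_score == 8
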