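import numpy as np
import pytest

from tissuemech.anatomy import AnatomyModel, LayerSpec, builtin_model, make_variants
from tissuemech.materials import MaterialParams
from tissuemech.meshing import build_mesh
from tissuemech.study import solve_condition


def single_layer_model(E=10.0, nu=0.3, thickness=10.0, radius=20.0, indenter=None, name="slab"):
    """Homogeneous benchmark column/halfspace model."""
    mat = MaterialParams(name, E=E, nu=nu)
    return AnatomyModel(
        model_id="custom",
        layers=(LayerSpec(name, thickness, mat),),
        domain_half_width=radius,
        indenter_radius=radius if indenter is None else indenter,
        roi_radius=radius,
    )


@pytest.fixture(scope="session")
def model1():
    return builtin_model("model1")


@pytest.fixture(scope="session")
def mesh_m1_coarse(model1):
    return build_mesh(model1, "coarse")


@pytest.fixture(scope="session")
def solved_m1_coarse(model1, mesh_m1_coarse):
    """Model 1 at 10 kPa, coarse mesh, default traction loading."""
    return solve_condition(model1, 10.0, mesh=mesh_m1_coarse)


@pytest.fixture(scope="session")
def mini_study():
    """Coarse sensor-loaded sweep used by the trend assertions.

    Both models at 2, 8 and 10 kPa baseline plus the softened variants at
    10 kPa, with thresholds from Model 1 baseline.
    """
    from tissuemech.exposure import exposure_report, reference_thresholds

    tables = {}
    for model_id in ("model1", "model2"):
        base = builtin_model(model_id)
        mesh = build_mesh(base, "coarse")
        for p in (2.0, 8.0, 10.0):
            tables[(model_id, p, 1.0)] = solve_condition(base, p, mesh=mesh, contact_mode="rigid_punch").table
        for var in make_variants(base, (0.1, 0.2)):
            tables[(model_id, 10.0, var.stiffness_factor)] = solve_condition(
                var, 10.0, mesh=mesh, contact_mode="rigid_punch"
            ).table
    thresholds = reference_thresholds({10.0: tables[("model1", 10.0, 1.0)]})
    report = exposure_report(tables, thresholds)
    return {"tables": tables, "thresholds": thresholds, "report": report}
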