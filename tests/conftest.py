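"""Shared fixtures: expensive synthetic constructions are session-scoped."""

import numpy as np
import pytest

from vertemorph import align, hexssm, meshkit, ssm_tri
from vertemorph.assembly import make_ivd_template


@pytest.fixture(scope="session")
def ivd_template():
    """Calibrated synthetic IVD hex template (built once per session)."""
    return make_ivd_template()


@pytest.fixture(scope="session")
def spine_bundle():
    """Synthetic spine cohort -> GPA -> triangulated SSM -> hex SSM.

    Returns a dict with the family, registries, fitted models and the
    transferred hexahedral shape model.
    """
    shapes, registry = meshkit.make_spine_family(n=14, seed=3)
    res = align.gpa(shapes)
    model = ssm_tri.fit_model(res.aligned, m=5)
    mean_shape = model.mean_shape()
    hex_mean, node_registry = meshkit.make_spine_fe_template(mean_shape, registry)
    fields = hexssm.transfer_fields(model, mean_shape, hex_mean,
                                    rigid_align=False)
    hex_model = hexssm.HexShapeModel(hex_mean=hex_mean, fields=fields)
    return {
        "shapes": shapes,
        "registry": registry,
        "gpa": res,
        "model": model,
        "mean_shape": mean_shape,
        "hex_mean": hex_mean,
        "node_registry": node_registry,
        "hex_model": hex_model,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
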