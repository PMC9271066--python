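import numpy as np
import pytest
import trimesh

from kneessfm.geometry import PointCloud, TriangleMesh
from kneessfm.pipeline import PipelineConfig, run_pipeline
from kneessfm.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def icosphere_r20():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces), "sphere")


@pytest.fixture(scope="session")
def planar_patch():
    """10 x 10 mm square patch in the z = 0 plane, CCW seen from +z."""
    verts = np.array(
        [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], dtype=float
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(verts, faces, "patch")


@pytest.fixture(scope="session")
def recovery_cohort():
    """The structure-recovery study cohort: n = 60, three latent modes at
    60/25/10% variance shares, 5% noise, fixed seed."""
    return generate_cohort(default_config(n_subjects=60, seed=7))


@pytest.fixture(scope="session")
def recovery_result(recovery_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("recovery_run")
    cfg = PipelineConfig(correspondence="builtin", output_dir=str(out), seed=7)
    return run_pipeline(cfg, cohort=recovery_cohort)
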