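import numpy as np
import pandas as pd
import pytest

from muscleshape import SurfaceMesh, generate_muscle_mesh


@pytest.fixture
def unit_tetrahedron() -> SurfaceMesh:
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh("tetra", v, f)


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    v = np.array([[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0)
                  for z in (0.0, 1.0)])
    # 12 triangles, outward winding
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0
        [4, 7, 5], [4, 6, 7],          # x = 1
        [0, 4, 5], [0, 5, 1],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return SurfaceMesh("cube", v, f)


@pytest.fixture
def icosphere() -> SurfaceMesh:
    import trimesh
    tm = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
    return SurfaceMesh("sphere", np.asarray(tm.vertices),
                       np.asarray(tm.faces))


@pytest.fixture
def muscle_mesh() -> SurfaceMesh:
    """Medium-resolution noiseless synthetic muscle."""
    return generate_muscle_mesh(250.0, 60.0, 30.0, n_vertices=500,
                                rng=np.random.default_rng(0),
                                specimen_id="muscle")


def make_covariates(rng: np.random.Generator, n: int = 30) -> pd.DataFrame:
    """Covariate table with realistic marginals and no built-in effects."""
    n_young = n // 2
    grp = ["young"] * n_young + ["older"] * (n - n_young)
    sex = (["female", "male"] * n)[:n]
    h = rng.normal(170.0, 8.0, n)
    return pd.DataFrame({
        "specimen_id": [f"S{i:03d}" for i in range(n)],
        "age_group": grp,
        "sex": sex,
        "height": h,
        "mass": 24.0 * (h / 100.0) ** 2 * np.exp(rng.normal(0, 0.1, n)),
        "volume": rng.lognormal(5.0, 0.2, n),
        "metmin": rng.lognormal(7.5, 0.5, n),
    })


@pytest.fixture
def covariates() -> pd.DataFrame:
    return make_covariates(np.random.default_rng(42))
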