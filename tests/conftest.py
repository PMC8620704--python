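import numpy as np
import pytest

from cellcom import CellGeneratorSpec, CellRecord, ReceptorObject, StudyGroup, generate_cells


@pytest.fixture(scope="session")
def small_group() -> StudyGroup:
    """12 synthetic cells with fast-to-generate settings."""
    spec = CellGeneratorSpec(n_objects_mean=40.0, n_nucleus_objects=8, seed=11)
    return generate_cells(spec, 12)


@pytest.fixture(scope="session")
def source_group() -> StudyGroup:
    """Default-parameter source group at the study's group size."""
    return generate_cells(CellGeneratorSpec(seed=42), 36)


def random_cell(rng: np.random.Generator, n_objects: int = 20,
                cell_id: str = "r") -> CellRecord:
    """A cell with uniformly random positions, volumes, and intensities."""
    objs = [
        ReceptorObject(
            x=float(rng.uniform(0, 100)),
            y=float(rng.uniform(0, 100)),
            z=float(rng.uniform(0, 20)),
            n_voxels=int(rng.integers(1, 200)),
            mean_intensity=float(rng.uniform(0.1, 500)),
        )
        for _ in range(n_objects)
    ]
    ref = rng.uniform(0, 100, size=3)
    return CellRecord(cell_id=cell_id, objects=objs, reference_point=ref)
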