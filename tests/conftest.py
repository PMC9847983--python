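import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def cube_stl(tmp_path):
    """A unit-cube ASCII STL on disk."""
    import trimesh

    path = tmp_path / "cube.stl"
    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    tm.apply_translation((0.5, 0.5, 0.5))
    path.write_bytes(trimesh.exchange.stl.export_stl_ascii(tm).encode())
    return path
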