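import pytest
from hypothesis import settings

from venomstrat import synthetic_data as sd
from venomstrat.phylostrat import SpeciesTree

settings.register_profile("default", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_tree() -> SpeciesTree:
    """The 14-taxon demo topology with the robber fly as focal leaf."""
    return sd.default_tree()


@pytest.fixture(scope="session")
def quiet_params() -> sd.SimulationParams:
    """Near-noise-free simulation: tiny dispersion, no losses, full detection."""
    return sd.SimulationParams(loss_prob=0.0, dispersion=1e-6, detection_prob=1.0)


@pytest.fixture(scope="session")
def quiet_bundle(quiet_params) -> sd.Bundle:
    return sd.generate_bundle(params=quiet_params, seed=11)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, quiet_bundle):
    """The quiet bundle written to disk, plus a ready-to-run config file."""
    import yaml

    out = tmp_path_factory.mktemp("bundle")
    paths = sd.write_bundle(quiet_bundle, out)
    meta = sd._sample_meta()
    cfg = {
        "focal": sd.DEFAULT_FOCAL,
        "inputs": {
            "tree": str(paths["tree"]),
            "orthogroups": str(paths["orthogroups"]),
            "gff3": str(paths["gff3"]),
            "repeats": str(paths["repeats"]),
            "hits": str(paths["hits"]),
            "venom_proteins": str(paths["venom_proteins"]),
            "quant": {
                s: {
                    "path": str(p),
                    "tissue": meta.loc[s, "tissue"],
                    "sex": meta.loc[s, "sex"],
                }
                for s, p in paths["quant"].items()
            },
        },
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return {"dir": out, "paths": paths, "config": cfg_path, "config_dict": cfg}
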