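import logging

import pytest

from orthonet.pipeline import PipelineConfig, run_pipeline
from orthonet.synthetic import simulate_bundle

logging.disable(logging.WARNING)


def bundle_config(bundle: dict, outdir: str, seed: int) -> PipelineConfig:
    return PipelineConfig(
        datasets=[
            {"id": ds_id, "matrix": p["matrix"], "groups": p["groups"]}
            for ds_id, p in bundle["datasets"].items()
        ],
        human_edges=bundle["human_edges"],
        worm_edges=bundle["worm_edges"],
        orthologs=[{"path": bundle["orthologs"], "label": "synthetic"}],
        human_gmt=bundle["human_gmt"],
        worm_gmt=bundle["worm_gmt"],
        outdir=outdir,
        seed=seed,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(outdir, seed=1)


@pytest.fixture(scope="session")
def bundle_manifest(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    config = bundle_config(bundle, str(outdir), seed=1)
    return run_pipeline(config)
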