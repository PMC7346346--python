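import pytest

from phenomine import (
    PipelineConfig,
    gen_screen_world,
    run_pipeline,
)


def world_config(world, out_dir, **overrides) -> PipelineConfig:
    """PipelineConfig wired to a generated synthetic world."""
    base = dict(
        labels_dir=str(world.labels_dir),
        train_dir=str(world.train_dir),
        lexicon=str(world.lexicon),
        blast_tsv=str(world.blast_tsv),
        mapping_tsv=str(world.mapping_tsv),
        string_tsv=str(world.string_tsv),
        obo=str(world.obo),
        gene2pheno_tsv=str(world.gene2pheno_tsv),
        gaf=str(world.gaf),
        go_names_tsv=str(world.go_names_tsv),
        output_dir=str(out_dir),
        seed=world.seed,
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def screen_world(tmp_path_factory):
    """One seed-11 synthetic screen world shared across the session."""
    root = tmp_path_factory.mktemp("world11")
    return gen_screen_world(root, seed=11)


@pytest.fixture(scope="session")
def pipeline_run(screen_world, tmp_path_factory):
    """(world, triples, report, model_path) of one full pipeline run.

    The trained CRF archive is saved so other tests can rerun the
    cascade without retraining.
    """
    out = tmp_path_factory.mktemp("out11")
    model_path = out / "model.json"
    cfg = world_config(screen_world, out, model_path=str(model_path))
    triples, report = run_pipeline(cfg)
    return screen_world, triples, report, model_path
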