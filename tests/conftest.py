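import logging

import pytest
from hypothesis import settings

import divergelens as dl

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

logging.getLogger("divergelens").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_genome():
    """The default synthetic genome with expression, QC-filtered and joined."""
    cfg = dl.SynthConfig()
    loci, truth = dl.generate_genome(cfg)
    expression = dl.generate_expression(loci, truth, cfg)
    filtered, filter_log = dl.apply_qc_filters(loci)
    expression = dl.present_calls(expression)
    table = dl.join_analysis_table(filtered, expression, n_samples=cfg.n_samples)
    geb = dl.geb_counts(expression, "rnaseq_rpm", n_samples=cfg.n_samples)
    table["geb"] = table["locus_id"].map(geb).fillna(0).astype(int)
    table["breadth_class"] = dl.classify_breadth(table["geb"])
    return {
        "config": cfg,
        "loci": loci,
        "truth": truth,
        "expression": expression,
        "filtered": filtered,
        "filter_log": filter_log,
        "table": table,
    }


@pytest.fixture(scope="session")
def small_genome():
    """A small genome for structural tests where couplings do not matter."""
    cfg = dl.SynthConfig(n_loci=2000, seed=11)
    loci, truth = dl.generate_genome(cfg)
    expression = dl.generate_expression(loci, truth, cfg)
    return {"config": cfg, "loci": loci, "truth": truth, "expression": expression}
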