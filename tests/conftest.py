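import pytest

from mmreg import pipeline, synthetic_data as sd
from mmreg.intervals import GeneModel, GenomicInterval


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory):
    """The default synthetic corpus (seed 7) shared across the suite."""
    d = tmp_path_factory.mktemp("corpus")
    cfg = sd.GeneratorConfig(seed=7)
    truth = sd.generate(cfg, d)
    return d, cfg, truth


@pytest.fixture(scope="session")
def pipeline_run(default_corpus, tmp_path_factory):
    """A full pipeline run over the default corpus."""
    corpus_dir, _, _ = default_corpus
    out = tmp_path_factory.mktemp("run")
    summary = pipeline.run_all(corpus_dir, out)
    return out, summary


def make_gene(gene_id, chrom, start, end, strand="+", exons=()):
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end),
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )
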