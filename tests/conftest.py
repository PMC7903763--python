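import pytest

from gliomareport.model import AnalysisConfig, AnnotatedVariant
from gliomareport.synthetic import TruthSpec, build_catalogs, build_gene_models, generate_case


@pytest.fixture(scope="session")
def catalogs():
    return build_catalogs()


@pytest.fixture(scope="session")
def gene_models():
    return build_gene_models()


@pytest.fixture
def cfg():
    return AnalysisConfig(coding_mb=30.0)


@pytest.fixture(scope="session")
def default_case(tmp_path_factory):
    """One generated synthetic case (files on disk + truth manifest)."""
    d = tmp_path_factory.mktemp("case")
    manifest = generate_case(TruthSpec(seed=11), d)
    return d, manifest


def make_variant(origin="somatic", **kw):
    """Terse variant factory for unit tests."""
    base = dict(
        chrom="chr1", pos=1000, ref="A", alt="G", gene="GENEX",
        classification="Missense_Mutation", origin=origin,
        tumor_vaf=0.3, tumor_depth=100, normal_depth=40,
    )
    if origin == "germline":
        base.update(tumor_vaf=None, tumor_depth=0)
    base.update(kw)
    return AnnotatedVariant(**base)
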