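import pytest

from snosplice import annotation as ann
from snosplice import junction_fold as jf
from snosplice import synthetic as syn

#: seed of the standard fixture locus; all derived expectations
#: (conditional verdicts, mutant outcomes) were verified for this seed
FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def mam_locus():
    """The standard two-exon host: intronic snoRNA, exonic snoRNA, 25-bp
    arms crossing the last junction 15 nt into exon 1."""
    return syn.make_locus(syn.LocusSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def mam_assets(mam_locus):
    return ann.parse_annotation(mam_locus.gff3, mam_locus.fasta)


@pytest.fixture(scope="session")
def mam_models(mam_assets):
    return ann.build_transcript_models(mam_assets)


@pytest.fixture(scope="session")
def mam_window(mam_models, mam_assets):
    return jf.extract_junction_window(mam_models[0], mam_assets)


@pytest.fixture(scope="session")
def mam_hairpin(mam_window):
    hairpin = jf.detect_junction_hairpin(mam_window)
    assert hairpin is not None
    return hairpin


def analyze_locus(locus, require_crossing=False):
    """Full single-locus analysis used across tests: returns
    (window, hairpin-or-None, verdict-or-None)."""
    assets = ann.parse_annotation(locus.gff3, locus.fasta)
    models = ann.build_transcript_models(assets)
    model = next(m for m in models if m.id == locus.truth.host_transcript_id)
    window = jf.extract_junction_window(model, assets)
    hairpin = jf.detect_junction_hairpin(window,
                                         require_crossing=require_crossing)
    verdict = (jf.conditionality_test(window, hairpin)
               if hairpin is not None else None)
    return window, hairpin, verdict
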