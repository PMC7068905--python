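import numpy as np
import pytest

from uorfkit.genome_annotation import (
    GenomeSequence,
    SplicedCDNA,
    load_annotation,
    select_representative,
)
from uorfkit.synthetic_fixtures import FixtureConfig, generate_fixture
from uorfkit.variant_engine import filter_variants


def make_spliced(seq, morf_start, morf_end, transcript_id="toy", strand="+", offset=0):
    """SplicedCDNA over an identity genome map starting at ``offset``."""
    n = len(seq)
    if strand == "+":
        gmap = np.arange(offset, offset + n, dtype=np.int64)
    else:
        gmap = np.arange(offset + n - 1, offset - 1, -1, dtype=np.int64)
    return SplicedCDNA(
        transcript_id=transcript_id,
        contig="chr1",
        strand=strand,
        seq=seq,
        morf_start=morf_start,
        morf_end=morf_end,
        genome_map=gmap,
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("universe")
    generate_fixture(FixtureConfig(n_genes=10, n_accessions=20, seed=11), d)
    return d


@pytest.fixture(scope="session")
def universe(fixture_dir):
    """A fully loaded synthetic universe: genome, models, calls, truth."""
    import json

    genome = GenomeSequence.from_fasta(fixture_dir / "genome.fa")
    models, excluded = load_annotation(fixture_dir / "annotation.gff3", genome)
    representative, _ = select_representative(models)
    calls, samples = filter_variants(str(fixture_dir / "variants.vcf"))
    truth = json.loads((fixture_dir / "truth_population.json").read_text())
    truth_ref = json.loads((fixture_dir / "truth_reference.json").read_text())
    return {
        "dir": fixture_dir,
        "genome": genome,
        "models": models,
        "excluded": excluded,
        "representative": representative,
        "calls": calls,
        "samples": samples,
        "truth": truth,
        "truth_reference": truth_ref,
    }
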