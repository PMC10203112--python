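import pytest

from stopcall import sim_data


@pytest.fixture(scope="session")
def toy():
    """A seeded toy genome with planted editable codons."""
    cfg = sim_data.SimConfig(seed=11)
    genome, transcripts, truth = sim_data.make_toy_genome(cfg)
    return genome, transcripts, truth


@pytest.fixture(scope="session")
def toy_amplicon(toy):
    """An amplicon reference around the first planted guide of the toy genome."""
    from stopcall.cli import amplicon_ref_from_candidate
    from stopcall.stop_designer import find_guides

    genome, transcripts, truth = toy
    row = truth.iloc[0]
    t = next(x for x in transcripts if x.transcript_id == row["transcript_id"])
    cands = find_guides(t, genome)
    cand = next(
        c
        for c in cands
        if c.interval[0] == row["proto_start"] and c.strand == row["proto_strand"]
    )
    return amplicon_ref_from_candidate(cand, genome)
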