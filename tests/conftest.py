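import numpy as np
import pytest

from viropop.core_io import AlignmentRecord, ContigRecord, CoverageTrack


@pytest.fixture
def make_aln():
    """Factory for AlignmentRecord with full-length defaults."""

    def _make(
        query_id,
        target_id,
        query_len,
        target_len,
        ani=1.0,
        query_cov=1.0,
        query_start=0,
        target_start=0,
    ):
        span = int(round(query_cov * query_len))
        matches = int(round(ani * span))
        return AlignmentRecord(
            query_id=query_id,
            target_id=target_id,
            query_start=query_start,
            query_end=query_start + span,
            target_start=target_start,
            target_end=target_start + span,
            n_matches=matches,
            aln_len=span,
            pct_identity=matches / span,
            query_len=query_len,
            target_len=target_len,
        )

    return _make


@pytest.fixture
def make_contig():
    def _make(contig_id, length, source_tech="short_read"):
        return ContigRecord(contig_id, None, length, source_tech=source_tech)

    return _make


@pytest.fixture
def make_track():
    def _make(depths, contig_id="c1"):
        return CoverageTrack(contig_id, np.asarray(depths))

    return _make
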