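import pytest

from mbcprimer.msa import (
    EXCLUSION,
    TARGET,
    AlignedRecord,
    Alignment,
    mask_terminal_gaps,
    trim_columns,
)


def make_alignment(target_rows, exclusion_rows, masked=True):
    """Build an Alignment directly from row strings (targets first)."""
    records = [
        AlignedRecord(id=f"t{i}", residues=row, set_label=TARGET)
        for i, row in enumerate(target_rows)
    ] + [
        AlignedRecord(id=f"e{i}", residues=row, set_label=EXCLUSION)
        for i, row in enumerate(exclusion_rows)
    ]
    n_cols = len(records[0].residues)
    aln = Alignment(records=records, n_columns=n_cols)
    if masked:
        mask_terminal_gaps(aln)
    return aln


def make_trimmed(target_rows, exclusion_rows, max_frac=0.20):
    return trim_columns(make_alignment(target_rows, exclusion_rows), max_frac)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
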