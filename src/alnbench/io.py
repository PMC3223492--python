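"""Import/export of test sets and alignments in plain-text formats."""

from __future__ import annotations

from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aligners import GAP, PairwiseAlignment
from .evolver import TestSet


def export_test_set(ts: TestSet, prefix: str | Path, set_id: str = "set0") -> None:
    """Write a test set as FASTA + reference/core TSVs + a YAML config echo.

    Files written: ``<prefix>.fasta`` (two records per pair, IDs
    ``<set_id>|p<k>|s1`` / ``s2``), ``<prefix>.reference.tsv`` (pair_id, i, j;
    0-based full-sequence coordinates), ``<prefix>.cores.tsv`` (pair_id, seq,
    start, end; half-open) and ``<prefix>.yaml``.
    """
    prefix = Path(prefix)
    records = []
    for k, pair in enumerate(ts.pairs):
        pid = f"{set_id}|p{k}"
        records.append(SeqRecord(Seq(pair.seq1), id=f"{pid}|s1", description=""))
        records.append(SeqRecord(Seq(pair.seq2), id=f"{pid}|s2", description=""))
    SeqIO.write(records, str(prefix) + ".fasta", "fasta")
    with open(str(prefix) + ".reference.tsv", "w") as fh:
        fh.write("pair_id\ti\tj\n")
        for k, pair in enumerate(ts.pairs):
            for i, j in pair.reference:
                fh.write(f"{set_id}|p{k}\t{i}\t{j}\n")
    with open(str(prefix) + ".cores.tsv", "w") as fh:
        fh.write("pair_id\tseq\tstart\tend\n")
        for k, pair in enumerate(ts.pairs):
            fh.write(f"{set_id}|p{k}\ts1\t{pair.core1[0]}\t{pair.core1[1]}\n")
            fh.write(f"{set_id}|p{k}\ts2\t{pair.core2[0]}\t{pair.core2[1]}\n")
    cfg = dict(set_id=set_id, n_pairs=ts.n_pairs, seed=ts.seed,
               pam=ts.params.pam, p_del=ts.params.p_del,
               zipf_exponent=ts.params.zipf_exponent,
               max_indel_len=ts.params.max_indel_len,
               ancestor_length=ts.params.ancestor_length,
               r=ts.spec.r, c=ts.spec.c)
    with open(str(prefix) + ".yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_fasta_pair(path: str | Path) -> tuple[str, str]:
    """Read a 2-record FASTA as an alignment input pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 FASTA records, got {len(records)}")
    return str(records[0].seq), str(records[1].seq)


def alignment_to_fasta(alignment: PairwiseAlignment, s1: str, s2: str,
                       path: str | Path, ids: tuple[str, str] = ("s1", "s2")) -> None:
    """Write an alignment as gapped FASTA ('-' for gaps)."""
    row1 = "".join("-" if i == GAP else s1[i] for i, _ in alignment.columns)
    row2 = "".join("-" if j == GAP else s2[j] for _, j in alignment.columns)
    records = [SeqRecord(Seq(row1), id=ids[0], description=""),
               SeqRecord(Seq(row2), id=ids[1], description="")]
    SeqIO.write(records, str(path), "fasta")


def alignment_to_tsv(alignment: PairwiseAlignment, path: str | Path) -> None:
    """Write alignment columns as TSV (i, j; -1 marks a gap)."""
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for i, j in alignment.columns:
            fh.write(f"{i}\t{j}\n")
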