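"""File-format plumbing: FASTA/FASTQ in, TSV/JSON/BED out.

All text outputs are deterministic and carry a comment header echoing the
configuration that produced them, so a result file documents its own run.
FASTQ readers are gzip-transparent on the ``.gz`` suffix.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import EditingStats, IndelCall
from .geometry import NickSite, PairGeometry, ProtospacerSite
from .simulate import SimulatedRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "site_table",
    "pair_table",
    "call_table",
    "write_table",
    "write_json_record",
    "nicks_to_bed",
]

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: PathLike) -> dict[str, str]:
    """All records of a FASTA file as {id: uppercase sequence}."""
    with _open_text(path, "r") as fh:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: PathLike, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    with _open_text(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path: PathLike) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (read_id, sequence, phred_qualities); Phred+33, gz-transparent."""
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper(), \
                rec.letter_annotations["phred_quality"]


def write_fastq(path: PathLike, reads: Sequence[SimulatedRead]) -> None:
    with _open_text(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quals}\n")


def site_table(sites: Sequence[ProtospacerSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"reference_id": s.reference_id, "start": s.start, "end": s.end,
          "strand": s.strand, "spacer_seq": s.spacer_seq, "pam_seq": s.pam_seq}
         for s in sites],
        columns=["reference_id", "start", "end", "strand",
                 "spacer_seq", "pam_seq"])


def pair_table(pairs: Sequence[PairGeometry],
               verdict_rows: Optional[Sequence[dict]] = None) -> pd.DataFrame:
    """Pair geometry (optionally merged with viability/stimulation columns)."""
    rows = []
    for i, g in enumerate(pairs):
        row = {
            "pair_id": f"pair{i:04d}",
            "reference_id": g.site_a.reference_id,
            "variant": g.variant,
            "site_a_start": g.site_a.start, "site_a_strand": g.site_a.strand,
            "site_b_start": g.site_b.start, "site_b_strand": g.site_b.strand,
            "nick_a_junction": g.nick_a.junction,
            "nick_b_junction": g.nick_b.junction,
            "inter_nick_distance": g.inter_nick_distance,
            "overlap_length": g.overlap_length,
            "overhang_polarity": g.overhang_polarity,
            "overhang_length": g.overhang_length,
        }
        if verdict_rows is not None:
            row.update(verdict_rows[i])
        rows.append(row)
    cols = ["pair_id", "reference_id", "variant", "site_a_start",
            "site_a_strand", "site_b_start", "site_b_strand",
            "nick_a_junction", "nick_b_junction", "inter_nick_distance",
            "overlap_length", "overhang_polarity", "overhang_length"]
    if verdict_rows:
        cols += [c for c in verdict_rows[0] if c not in cols]
    return pd.DataFrame(rows, columns=cols)


def call_table(calls: Sequence[IndelCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c.deletions:
            for s, e in c.deletions:
                rows.append({"read_id": c.read_id, "edit_class": c.edit_class,
                             "del_start": s, "del_end": e,
                             "ins_point": c.insertion_point,
                             "ins_len": len(c.insertion_seq),
                             "ins_seq": c.insertion_seq})
        else:
            rows.append({"read_id": c.read_id, "edit_class": c.edit_class,
                         "del_start": None, "del_end": None,
                         "ins_point": c.insertion_point,
                         "ins_len": len(c.insertion_seq),
                         "ins_seq": c.insertion_seq})
    return pd.DataFrame(rows, columns=["read_id", "edit_class", "del_start",
                                       "del_end", "ins_point", "ins_len",
                                       "ins_seq"])


def calls_from_table(df: pd.DataFrame) -> list[IndelCall]:
    """Rebuild IndelCall objects from a call table (inverse of call_table)."""
    calls: list[IndelCall] = []
    for read_id, group in df.groupby("read_id", sort=False):
        first = group.iloc[0]
        dels = tuple(sorted(
            (int(r.del_start), int(r.del_end))
            for r in group.itertuples()
            if pd.notna(r.del_start)))
        ins_seq = "" if pd.isna(first.ins_seq) or first.ins_seq == "" \
            else str(first.ins_seq)
        ins_point = None if pd.isna(first.ins_point) else int(first.ins_point)
        calls.append(IndelCall(str(read_id), str(first.edit_class), dels,
                               ins_seq, ins_point))
    return calls


def _header_lines(config: Optional[dict]) -> str:
    from . import __version__
    lines = [f"# nickpair {__version__}"]
    for key, val in sorted((config or {}).items()):
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def write_table(path: PathLike, df: pd.DataFrame,
                config: Optional[dict] = None) -> None:
    """TSV with a '#'-comment header echoing the run configuration."""
    with _open_text(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json_record(path: PathLike, record: dict,
                      config: Optional[dict] = None) -> None:
    from . import __version__
    payload = {"version": __version__}
    if config is not None:
        payload["config"] = config
    payload.update(record)
    with _open_text(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def nicks_to_bed(path: PathLike, nicks: Sequence[NickSite]) -> None:
    """Nick junctions as 0-width BED intervals (0-based, half-open)."""
    with _open_text(path, "w") as fh:
        for n in nicks:
            fh.write(f"{n.source_site.reference_id}\t{n.junction}\t"
                     f"{n.junction}\tnick_{n.variant}\t0\t{n.strand_nicked}\n")
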