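"""Plain-text genomics I/O: FASTA, BED6, dataset manifests."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .dataset import GenomicInterval, LabeledDHS


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """BED6: chrom, start, end, name, score(0), strand."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"feature{i}"
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        strand = parts[5] if len(parts) > 5 else "."
        out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


MANIFEST_COLUMNS = ["id", "chrom", "start", "end", "strand", "label", "source", "split"]


def write_manifest(
    samples: Sequence[LabeledDHS],
    path: str | Path,
    splits: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(samples):
        rows.append(
            {
                "id": f"dhs{i}",
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "strand": s.interval.strand,
                "label": s.label,
                "source": s.source,
                "split": splits.get(i, "") if splits else "",
            }
        )
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    frame.to_csv(path, index=False)
    return frame


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)
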