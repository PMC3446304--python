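"""Reading and writing the pipeline's file formats.

GFF3 (1-based inclusive), bedGraph (0-based half-open), FASTA, and the
plain-TSV interchange tables used between pipeline stages. TSVs written by
the pipeline carry ``#``-prefixed header lines recording tool version,
config hash and seed, which pandas skips on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CoverageTrack, GeneRecord

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def _format_attributes(gene: GeneRecord) -> str:
    parts = [f"ID={gene.gene_id}"]
    if np.isfinite(gene.gc_fraction):
        parts.append(f"gc_fraction={gene.gc_fraction:.4f}")
    if gene.cog_class:
        parts.append(f"cog_class={gene.cog_class}")
    if gene.kegg_pathways:
        parts.append("kegg_pathways=" + ",".join(gene.kegg_pathways))
    if gene.rbs_sequence:
        parts.append(f"rbs_sequence={gene.rbs_sequence}")
    if gene.repeat_families:
        parts.append("repeat_families=" + ",".join(gene.repeat_families))
    if gene.is_pseudogene:
        parts.append("pseudo=true")
    if gene.operon_id:
        parts.append(f"operon_id={gene.operon_id}")
    return ";".join(parts)


def write_gff3(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as GFF3 CDS features (1-based inclusive)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fields = [
                g.replicon, "decaymap", "CDS",
                str(g.start + 1), str(g.end), ".",
                g.strand, "0", _format_attributes(g),
            ]
            fh.write("\t".join(fields) + "\n")


def _parse_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read CDS/gene features from a GFF3 file into GeneRecords."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    genes: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        if row.type not in ("CDS", "gene"):
            continue
        attrs = _parse_attributes(row.attributes)
        gene_id = attrs.get("ID") or attrs.get("locus_tag")
        if gene_id is None:
            raise ValueError(f"feature without ID in {path}: {row.attributes!r}")
        genes.append(GeneRecord(
            gene_id=gene_id,
            replicon=row.seqid,
            start=int(row.start) - 1,
            end=int(row.end),
            strand=row.strand,
            gc_fraction=float(attrs.get("gc_fraction", "nan")),
            cog_class=attrs.get("cog_class") or None,
            kegg_pathways=tuple(filter(None, attrs.get("kegg_pathways", "").split(","))),
            rbs_sequence=attrs.get("rbs_sequence") or None,
            repeat_families=tuple(filter(None, attrs.get("repeat_families", "").split(","))),
            is_pseudogene=attrs.get("pseudo", "").lower() == "true",
            operon_id=attrs.get("operon_id") or None,
        ))
    return genes


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as bedGraph (0-based half-open, zero runs omitted)."""
    v = track.values
    # run-length encode: boundaries where the value changes
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(v)]])
    with Path(path).open("w") as fh:
        fh.write(f"track type=bedGraph name={track.sample_name}\n")
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{track.replicon}\t{s}\t{e}\t{v[s]:g}\n")


_SAMPLE_RE = re.compile(r"(?P<strain>.+)_(?P<rep>[^_]+)_t(?P<time>[0-9p.]+)$")


def parse_sample_name(stem: str) -> tuple[str, str, float]:
    """Split ``<strain>_<rep>_t<min>`` into its components ('p' stands for '.')."""
    m = _SAMPLE_RE.match(stem)
    if m is None:
        raise ValueError(f"cannot parse sample name {stem!r}")
    t = float(m.group("time").replace("p", "."))
    return m.group("strain"), m.group("rep"), t


def read_bedgraph(path: str | Path, replicon_length: int,
                  replicon: str | None = None) -> CoverageTrack:
    """Read a bedGraph file into a dense per-base track of the given length.

    Sample metadata (strain, replicate, time) is recovered from the file stem
    when it follows the ``<strain>_<rep>_t<min>`` convention.
    """
    path = Path(path)
    values = np.zeros(replicon_length, dtype=float)
    name = None
    with path.open() as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            chrom, s, e, val = line.split("\t")
            if replicon is not None and chrom != replicon:
                continue
            name = name or chrom
            values[int(s):int(e)] = float(val)
    try:
        strain, rep, t = parse_sample_name(path.stem)
    except ValueError:
        strain, rep, t = "sample", "1", 0.0
    return CoverageTrack(replicon=replicon or name or "replicon",
                         values=values, strain=strain, replicate=rep, time_min=t)


def write_tsv(df: pd.DataFrame, path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write a TSV with optional '#'-prefixed metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
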