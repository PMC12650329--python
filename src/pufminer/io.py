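"""Readers and writers for the package's external formats.

FASTA goes through Bio.SeqIO; bin metadata is plain TSV via pandas; gene
features are GFF3 (1-based, inclusive, ``strand`` column honored) with the
controlled ``label`` vocabulary and any domain annotations carried in the
attributes column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneFeature, SeqRecordX

METADATA_COLUMNS = ["bin_id", "ecosystem_subtype", "temperature_c", "taxon", "source"]


def write_fasta(records: list[SeqRecordX], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.seq_id,
                             description=r.description) for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SeqRecordX]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(SeqRecordX(seq_id=rec.id, sequence=str(rec.seq), description=desc))
    return out


def write_bin_metadata(bins, path: str | Path) -> None:
    from .simulate import BinInfo  # local import to avoid a cycle
    rows = []
    for b in bins:
        rows.append({
            "bin_id": b.bin_id,
            "ecosystem_subtype": b.ecosystem_subtype,
            "temperature_c": "" if b.temperature_c is None else b.temperature_c,
            "taxon": b.taxon,
            "source": b.source,
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bin_metadata(path: str | Path):
    from .simulate import BinInfo
    df = pd.read_csv(path, sep="\t", dtype={"bin_id": str})
    out = []
    for _, row in df.iterrows():
        t = row["temperature_c"]
        temperature = None if pd.isna(t) or t == "" else float(t)
        out.append(BinInfo(
            bin_id=str(row["bin_id"]),
            temperature_c=temperature,
            ecosystem_subtype=str(row["ecosystem_subtype"]),
            taxon=str(row["taxon"]),
            source=str(row["source"])))
    return out


def metadata_frame(bins) -> pd.DataFrame:
    """Bin metadata as a DataFrame (the in-memory currency of curation)."""
    return pd.DataFrame([{
        "bin_id": b.bin_id,
        "ecosystem_subtype": b.ecosystem_subtype,
        "temperature_c": float("nan") if b.temperature_c is None else b.temperature_c,
        "taxon": b.taxon,
        "source": b.source,
    } for b in bins], columns=METADATA_COLUMNS)


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(features: list[GeneFeature], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for f in features:
        attrs = [f"ID={f.gene_id}", f"label={f.label}"]
        if f.domain_annotations:
            attrs.append("domain_annotations=" + ",".join(f.domain_annotations))
        lines.append("\t".join([
            f.contig_id, "pufminer", "gene", str(f.start), str(f.end),
            ".", f.strand, ".", ";".join(attrs)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneFeature]:
    import gffutils
    body = [ln for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
    if not body:
        return []
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    out = []
    for feat in db.all_features(order_by=("seqid", "start")):
        annots = feat.attributes.get("domain_annotations", [])
        if annots:
            annots = annots[0].split(",")
        out.append(GeneFeature(
            contig_id=feat.seqid,
            gene_id=feat.attributes["ID"][0],
            start=int(feat.start),
            end=int(feat.end),
            strand=feat.strand,
            label=feat.attributes.get("label", ["other"])[0],
            domain_annotations=annots))
    return out
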