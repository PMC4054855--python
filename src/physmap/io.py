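"""Plain-text readers and writers.

Band files follow the FPC ``.sizes`` convention: one record per clone, a
header line ``<clone name> <band count>`` followed by one band size per
line. Everything tabular goes through pandas TSV.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# band files

def write_band_file(fingerprints, path) -> None:
    with open(path, "w") as fh:
        for fp in fingerprints:
            fh.write(f"{fp.clone_id} {len(fp.bands)}\n")
            for size in fp.bands:
                fh.write(f"{size:.1f}\n")


def read_band_file(path) -> list:
    from .assembly import Fingerprint

    fingerprints = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) != 2:
            raise ValueError(f"malformed band-file header line: {lines[i]!r}")
        name, count = parts[0], int(parts[1])
        sizes = [float(x) for x in lines[i + 1:i + 1 + count]]
        if len(sizes) != count:
            raise ValueError(f"truncated band record for clone {name}")
        fingerprints.append(Fingerprint(clone_id=name,
                                        bands=np.sort(np.asarray(sizes))))
        i += 1 + count
    return fingerprints


# ---------------------------------------------------------------------------
# truth tables

def write_truth_tsv(chrom, clones, path) -> None:
    """BED-like truth table: id, start kb, end kb, class, attributes."""
    rows = []
    for clone in clones:
        rows.append((clone.id, clone.start, clone.end, "clone", "."))
    for gene in chrom.genes:
        attrs = "syntenic=%d" % gene.syntenic
        if gene.ortholog_refs:
            refs = ";".join(
                f"{g}:{c}:{i}" for g, (c, _gid, i) in sorted(gene.ortholog_refs.items())
            )
            attrs += "|" + refs
        rows.append((gene.id, gene.pos, gene.pos, "gene", attrs))
    for m in chrom.markers:
        rows.append((m.id, m.pos, m.pos, m.marker_class,
                     "polymorphic=%d" % m.polymorphic))
    pd.DataFrame(rows, columns=["id", "start_kb", "end_kb", "class", "attrs"]) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contigs / maps / hits

def write_contig_tsv(contigs, path) -> None:
    rows = [
        (c.id, clone_id, c.cb.get(clone_id, np.nan), int(c.validated), c.width)
        for c in contigs for clone_id in c.clones
    ]
    pd.DataFrame(rows, columns=["contig", "clone", "cb", "validated",
                                "width"]).to_csv(path, sep="\t", index=False)


def read_genetic_map_tsv(path):
    from .mapping import GeneticMapData

    df = pd.read_csv(path, sep="\t")
    return GeneticMapData(loci=list(df.iloc[:, 0]),
                          positions=list(df.iloc[:, 1].astype(float)))


def write_genetic_map_tsv(gmap, path) -> None:
    pd.DataFrame({"locus": gmap.loci, "cM": gmap.positions}) \
        .to_csv(path, sep="\t", index=False)


HIT_COLUMNS = ["query", "ref_genome", "ref_chr", "ref_gene", "ref_index",
               "pct_id", "aln_len", "coverage"]


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
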