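"""Reading and writing the pipeline's on-disk artifacts.

Tables are TSV, trees newick, sequences plain two-line FASTA (one CDS
file plus one structural-RNA file per species, RNA records tagged
``trna`` / ``rrna_5s`` / ``rrna_16s`` / ``rrna_23s``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import GenomeBundle

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_bundles",
    "read_bundles",
    "write_json",
    "file_sha256",
]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    def _default(o):
        if hasattr(o, "item"):
            return o.item()
        if isinstance(o, (set, tuple)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _records(pairs):
    for name, seq in pairs:
        yield SeqRecord(Seq(seq), id=name, description="")


def write_bundles(bundles: dict[str, GenomeBundle], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, b in bundles.items():
        d = out / sid
        d.mkdir(exist_ok=True)
        SeqIO.write(
            _records((f"{sid}|cds_{i + 1:04d}", s) for i, s in enumerate(b.cds)),
            d / "cds.fna",
            "fasta-2line",
        )
        rna = []
        if b.trna:
            for i, s in enumerate(t if isinstance((t := b.trna), list) else [t]):
                rna.append((f"{sid}|trna_{i + 1}", s))
        for name, seqs in (b.rrna or {}).items():
            for i, s in enumerate(seqs if isinstance(seqs, list) else [seqs]):
                rna.append((f"{sid}|rrna_{name}_{i + 1}", s))
        SeqIO.write(_records(rna), d / "rna.fna", "fasta-2line")
    return out


def read_bundles(in_dir: str | Path) -> dict[str, GenomeBundle]:
    bundles: dict[str, GenomeBundle] = {}
    for d in sorted(Path(in_dir).iterdir()):
        if not d.is_dir():
            continue
        sid = d.name
        cds = [str(r.seq) for r in SeqIO.parse(d / "cds.fna", "fasta")]
        trna: list[str] = []
        rrna: dict[str, list[str]] = {}
        if (d / "rna.fna").exists():
            for r in SeqIO.parse(d / "rna.fna", "fasta"):
                tag = r.id.split("|", 1)[1]
                if tag.startswith("trna"):
                    trna.append(str(r.seq))
                elif tag.startswith("rrna_"):
                    rrna.setdefault(tag[5:].rsplit("_", 1)[0], []).append(str(r.seq))
        bundles[sid] = GenomeBundle(sid, cds, trna or None, rrna)
    return bundles
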