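"""File formats and run provenance.

Tables are TSV (UTF-8, '.' decimal, empty cell = missing) with ``#``
header comments recording tool version, config hash and seed; models are
JSON; profiles persist as HMMER3 ASCII ``.hmm``.  FASTA identifiers are
the first whitespace-delimited token of the header line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO

from . import __version__
from .profiles import ProfileHMM, ProfileRegistry, TrainingSequence


class FormatError(ValueError):
    pass


def read_fasta(path) -> dict:
    """Ordered ``{id: residues}`` from a protein FASTA file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    out = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = str(rec.seq).upper()
    except Exception as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    return out


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, res in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(res), width):
                fh.write(res[i:i + width] + "\n")


def read_alignment(path, fmt: Optional[str] = None) -> list:
    """Aligned FASTA or Stockholm as rows of ``(id, aligned_seq)``."""
    path = Path(path)
    fmt = fmt or ("stockholm" if path.suffix in (".sto", ".stk", ".stockholm")
                  else "fasta")
    from Bio import AlignIO
    aln = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq)) for rec in aln]


def config_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def provenance_header(seed, cfg_payload=None) -> str:
    h = config_hash(cfg_payload or {})
    return (f"# gh9class {__version__}\n"
            f"# config_hash={h} seed={seed}\n")


def write_tsv(df: pd.DataFrame, path, seed=None, cfg_payload=None,
              index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, cfg_payload))
        df.to_csv(fh, sep="\t", index=index, na_rep="")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_score_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    return df.astype(float)


def write_json(payload, path, seed=None) -> None:
    body = {"tool": f"gh9class {__version__}", "seed": seed,
            "config_hash": config_hash(payload)}
    body.update(payload)
    Path(path).write_text(json.dumps(body, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    import numpy as np
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


def read_metadata(path) -> list:
    """Training metadata TSV (columns uid, class_label, organism) joined
    with sequences supplied separately."""
    return read_tsv(path).reset_index().to_dict("records")


def save_registry(registry: ProfileRegistry, outdir, seed=None) -> None:
    """Profiles as HMMER3 ASCII files plus a metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in registry.profiles:
        rows.append({"profile_id": p.profile_id, "scope": p.scope,
                     "class_label": p.class_label, "rep": p.rep,
                     "excluded_uid": p.excluded_uid or "",
                     "model_length": p.model_length})
        if p.hmm is not None:
            with open(outdir / f"{p.profile_id}.hmm", "wb") as fh:
                p.hmm.write(fh, binary=False)
    write_tsv(pd.DataFrame(rows).set_index("profile_id"),
              outdir / "registry.tsv", seed=seed)


def load_registry(outdir) -> ProfileRegistry:
    import pyhmmer
    outdir = Path(outdir)
    meta = read_tsv(outdir / "registry.tsv").fillna("")
    profiles = []
    for pid, row in meta.iterrows():
        hmm = None
        hmm_path = outdir / f"{pid}.hmm"
        if hmm_path.exists():
            with pyhmmer.plan7.HMMFile(str(hmm_path)) as fh:
                hmm = fh.read()
        profiles.append(ProfileHMM(
            str(pid), row["scope"], row["class_label"], row["rep"],
            excluded_uid=str(row["excluded_uid"]) or None,
            model_length=int(row["model_length"]), hmm=hmm))
    return ProfileRegistry(profiles)
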