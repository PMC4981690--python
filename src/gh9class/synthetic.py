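"""Synthetic GH9-like families and score fixtures with known ground truth.

Every pipeline stage is testable without downloads: the generators here
emulate the sequence architecture that separates the three subclasses —

* class A: an N-terminal transmembrane-like hydrophobic segment,
* class B: an N-terminal signal-peptide-like segment,
* class C: a signal-peptide-like segment plus an aromatic-rich (W/F/Y
  enriched) C-terminal module of 100–120 residues emulating CBM49 —

all sharing a common catalytic-core ancestor so that homology search
retains every class while the termini carry the class signal.  The core
is a random ancestor, not a real GH9 sequence: profile discrimination
only needs architecture differences plus shared-core homology.
Score-table and α/β generators provide controlled class separations for
the downstream statistics.  All outputs are byte-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import CLASSES, TrainingSequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "AILMFVW"  # TM-like composition
SIGNAL_CORE = "ALVFSC"  # hydrophobic h-region of a signal peptide
AROMATIC = "WFY"


@dataclass
class FamilySpec:
    """Shape of a generated three-class family."""

    n_per_class: int = 6
    core_length: int = 450
    tm_length: int = 23
    signal_length: int = 20
    cbm_length: int = 110
    substitution_rate: float = 0.05
    class_divergence: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 100 <= self.cbm_length <= 120:
            raise ValueError("cbm_length must lie in [100, 120]")
        for r in (self.substitution_rate, self.class_divergence):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


@dataclass
class ScoreTableSpec:
    """Controlled class-mean separations for a synthetic score table."""

    class_means: Mapping[str, float] = field(
        default_factory=lambda: {"A": 500.0, "B": 200.0, "C": 100.0})
    pair_sd: float = 5.0
    n_per_class: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair_sd < 0:
            raise ValueError("pair_sd must be >= 0")


def _random_protein(rng: np.random.Generator, length: int,
                    alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _aromatic_rich(rng: np.random.Generator, length: int,
                   aromatic_frac: float = 0.45) -> str:
    out = []
    for _ in range(length):
        pool = AROMATIC if rng.random() < aromatic_frac else AA20
        out.append(str(rng.choice(list(pool))))
    return "".join(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        chars[i] = str(rng.choice(list(AA20)))
    return "".join(chars)


def gen_families(spec: Optional[FamilySpec] = None) -> tuple:
    """Generate labelled class-architectured sequences and a truth table.

    Returns ``(sequences, truth)`` where ``sequences`` is a list of
    :class:`TrainingSequence` and ``truth`` a DataFrame with uid, class
    label, organism and segment coordinates.  Class members are mutated
    copies of a class archetype at ``substitution_rate`` per site.
    """
    spec = spec or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    ancestor = _random_protein(rng, spec.core_length)
    # each subclass is a paralogous lineage: its core diverges from the
    # shared ancestor, keeping homology detectable but separating the
    # class-specific profile scores by hundreds of bits, as in real
    # GH9 subclasses
    cores = {c: _mutate(rng, ancestor, spec.class_divergence) for c in CLASSES}
    tm = _random_protein(rng, spec.tm_length, HYDROPHOBIC)
    signal = "M" + _random_protein(rng, spec.signal_length - 1, SIGNAL_CORE)
    cbm = _aromatic_rich(rng, spec.cbm_length)
    archetype = {
        "A": tm + cores["A"],
        "B": signal + cores["B"],
        "C": signal + cores["C"] + cbm,
    }
    records = []
    truth_rows = []
    for cls in CLASSES:
        for k in range(spec.n_per_class):
            uid = f"SYN{cls}{k + 1:03d}"
            residues = _mutate(rng, archetype[cls], spec.substitution_rate)
            org = f"synthplant{(k % 3) + 1}"
            records.append(TrainingSequence(uid, cls, residues, org))
            truth_rows.append({"uid": uid, "class_label": cls, "organism": org,
                               "length": len(residues)})
    truth = pd.DataFrame(truth_rows).set_index("uid")
    return records, truth


def family_alignments(sequences: Sequence[TrainingSequence],
                      spec: FamilySpec, trim_stride: int = 100) -> tuple:
    """Column-padded full alignments for a generated family.

    Because generated sequences carry no indels, a faithful multiple
    alignment is obtained by placing each architecture's segments into
    fixed column blocks (TM | signal | core | CBM) and gap-filling blocks
    a class lacks.  The "1D" alignment spans all blocks; the "3D"
    alignment drops every ``trim_stride``-th column, emulating a
    structure-guided alignment of the same sequences that trims loop
    positions — close enough to the 1D model that the (1D, 3D) score
    pairs of a class stay tight, as they must for the β statistic to
    reflect between-class spacing rather than alignment-flavour noise.
    """
    t, s, c, m = spec.tm_length, spec.signal_length, spec.core_length, spec.cbm_length
    rows_1d = []
    rows_3d = []
    for rec in sequences:
        if rec.class_label == "A":
            tm_seg, sig_seg = rec.residues[:t], "-" * s
            core_seg, cbm_seg = rec.residues[t:t + c], "-" * m
        elif rec.class_label == "B":
            tm_seg, sig_seg = "-" * t, rec.residues[:s]
            core_seg, cbm_seg = rec.residues[s:s + c], "-" * m
        else:
            tm_seg, sig_seg = "-" * t, rec.residues[:s]
            core_seg = rec.residues[s:s + c]
            cbm_seg = rec.residues[s + c:s + c + m]
        full = tm_seg + sig_seg + core_seg + cbm_seg
        rows_1d.append((rec.uid, full))
        rows_3d.append((rec.uid, "".join(
            ch for i, ch in enumerate(full) if (i + 1) % trim_stride != 0)))
    return rows_1d, rows_3d


def gen_score_table(spec: Optional[ScoreTableSpec] = None) -> tuple:
    """Synthetic generic-mode score table plus ground-truth labels.

    Each class's (1D, 3D) score pair is drawn from
    Normal(class mean, pair_sd); the truth label is the class with the
    largest planted mean.  Column names follow the registry convention
    (``cls-A-1d`` ...).
    """
    spec = spec or ScoreTableSpec()
    rng = np.random.default_rng(spec.seed)
    truth_label = max(spec.class_means, key=lambda c: spec.class_means[c])
    rows = {}
    labels = {}
    for cls in CLASSES:
        for k in range(spec.n_per_class):
            sid = f"SIM{cls}{k + 1:03d}"
            row = {}
            for c in CLASSES:
                for rep in ("1d", "3d"):
                    row[f"cls-{c}-{rep}"] = spec.class_means[c] + (
                        rng.normal(0.0, spec.pair_sd) if spec.pair_sd > 0 else 0.0)
            rows[sid] = row
            labels[sid] = truth_label
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table, pd.Series(labels, name="truth")


#: default class-conditional alpha-triple means; their sums sit near the
#: fitted class centroids reported for curated training data
DEFAULT_ALPHA_MEANS = {
    "A": (3.00, 2.50, 2.63),
    "B": (1.30, 1.30, 1.31),
    "C": (2.30, 2.30, 2.35),
}


def gen_alpha_beta(n_per_class: int = 8, gamma: Sequence[float] = (1.0, 1.0, 1.0),
                   noise_sd: float = 0.0, seed: int = 0,
                   alpha_means: Optional[Mapping[str, Sequence[float]]] = None,
                   alpha_sd: float = 0.05) -> tuple:
    """Class-conditional α triples with linear targets.

    Targets are Σ γ_ij α_ij + Normal(0, noise_sd).  Returns
    ``(X, y, labels)`` with ``X`` of shape (3·n_per_class, 3) and labels
    aligned with rows.
    """
    if n_per_class * len(CLASSES) < 3:
        raise ValueError("need at least 3 samples overall")
    rng = np.random.default_rng(seed)
    means = alpha_means or DEFAULT_ALPHA_MEANS
    g = np.asarray(gamma, dtype=float)
    X = []
    labels = []
    for cls in CLASSES:
        mu = np.asarray(means[cls], dtype=float)
        for _ in range(n_per_class):
            X.append(np.clip(mu + rng.normal(0.0, alpha_sd, size=3), 0.0, None))
            labels.append(cls)
    X = np.array(X)
    y = X @ g
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return X, y, np.array(labels)
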