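"""Profile-HMM registry construction and per-sequence scoring.

Plant GH9 endoglucanases fall into three subclasses: A (membrane anchored),
B (secreted) and C (secreted, carrying a C-terminal CBM49 module).  The
classifier scores every query sequence against a registry of profile HMMs
built from a curated training set.  Three kinds of profiles live in the
registry:

* two *generic* profiles (class ``X``) built from the whole training set,
  used only as a permissive homolog screen;
* two profiles per class (``A``/``B``/``C``), one from a sequence-based
  ("1D") alignment and one from a structure-derived ("3D") alignment;
* for every training sequence, a (1D, 3D) pair of *leave-one-out* profiles
  built from the class alignment with that sequence removed, so that a
  training sequence can be scored without having contributed to the model
  that scores it.

Scores are best-region (best single domain) bit scores as reported by
HMMER; the per-class evidence for a sequence is the mean over the relevant
1D/3D profile pair(s).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import pyhmmer

CLASSES = ("A", "B", "C")
REPS = ("1D", "3D")

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class AlignmentError(ValueError):
    """Raised for empty, ragged or too-small multiple alignments."""


class RegistryError(ValueError):
    """Raised when a registry violates its structural invariants."""


class DegenerateScoreError(ValueError):
    """Raised when a sequence has no usable score for an entire class."""


@dataclass(frozen=True)
class TrainingSequence:
    """A curated training protein with a known subclass label."""

    uid: str
    class_label: str
    residues: str
    organism: str = ""

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}, got {self.class_label!r}")
        if not self.residues:
            raise ValueError("residues must be non-empty")
        bad = set(self.residues.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters in {self.uid}: {sorted(bad)}")


@dataclass
class ProfileHMM:
    """Metadata (and optionally the compiled model) for one profile.

    ``scope`` is ``generic`` (whole training set, class ``X``), ``class``
    (one subclass) or ``loocv`` (class alignment with ``excluded_uid``
    removed).  ``rep`` records which alignment flavour the profile came
    from; it is pure metadata — any aligned input is accepted as the
    "3D" member.
    """

    profile_id: str
    scope: str
    class_label: str
    rep: str
    excluded_uid: Optional[str] = None
    model_length: int = 0
    hmm: Optional[pyhmmer.plan7.HMM] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.scope not in ("generic", "class", "loocv"):
            raise ValueError(f"bad scope {self.scope!r}")
        if self.rep not in REPS:
            raise ValueError(f"bad rep {self.rep!r}")
        if self.scope == "loocv" and not self.excluded_uid:
            raise ValueError("loocv profile requires excluded_uid")
        if self.scope != "loocv" and self.excluded_uid:
            raise ValueError("excluded_uid only valid for loocv scope")
        expected = "X" if self.scope == "generic" else self.class_label
        if self.scope == "generic" and self.class_label != "X":
            raise ValueError("generic profiles carry class label 'X'")
        if self.scope != "generic" and self.class_label not in CLASSES:
            raise ValueError(f"bad class_label {self.class_label!r} for scope {self.scope}")
        del expected


@dataclass
class SearchConfig:
    """E-value thresholds and score kind for HMM searches.

    ``e_class`` gates reporting against class and leave-one-out profiles
    (default 1e-6, seven orders of magnitude stricter than the generic
    homolog screen at ``e_generic`` = 10).  Scores are best single-region
    bit scores unless ``score_kind`` is set to ``"sequence"``.
    """

    e_class: float = 1e-6
    e_generic: float = 10.0
    score_kind: str = "domain"

    def __post_init__(self) -> None:
        if not (0 < self.e_class < self.e_generic):
            raise ValueError("need 0 < e_class < e_generic")
        if self.score_kind not in ("domain", "sequence"):
            raise ValueError("score_kind must be 'domain' or 'sequence'")


class LoocvSelection(NamedTuple):
    """Profiles retained when scoring one training sequence.

    All leave-one-out profiles of the two *other* classes are kept, plus
    the single (1D, 3D) pair of the target's own class that excludes the
    target.  ``delta_fraction`` is the retained count over the total
    class-specific profile count (all leave-one-out profiles plus the six
    class-level profiles).
    """

    target_uid: str
    target_class: str
    retained_profile_ids: tuple
    delta_fraction: float


class MaxClassResult(NamedTuple):
    label: Optional[str]
    ambiguous: bool


@dataclass
class ClassMeanTriple:
    """Per-class mean profile scores (bits) for one sequence.

    ``side_means`` keeps the (1D-side mean, 3D-side mean) pair per class;
    the headline means pool all contributing scores of a class.  The two
    agree whenever every (1D, 3D) pair is complete.
    """

    hmm_a: float
    hmm_b: float
    hmm_c: float
    mode: str
    contributing: Mapping[str, tuple]
    side_means: Mapping[str, tuple]

    def as_dict(self) -> dict:
        return {"A": self.hmm_a, "B": self.hmm_b, "C": self.hmm_c}


@dataclass
class ProfileRegistry:
    """The full complement of profiles for one training set."""

    profiles: list

    def __post_init__(self) -> None:
        ids = [p.profile_id for p in self.profiles]
        dup = [k for k, v in Counter(ids).items() if v > 1]
        if dup:
            raise RegistryError(f"duplicate profile ids: {dup}")

    def by_id(self, profile_id: str) -> ProfileHMM:
        for p in self.profiles:
            if p.profile_id == profile_id:
                return p
        raise KeyError(profile_id)

    def select(self, scope: Optional[str] = None, class_label: Optional[str] = None,
               rep: Optional[str] = None) -> list:
        out = self.profiles
        if scope is not None:
            out = [p for p in out if p.scope == scope]
        if class_label is not None:
            out = [p for p in out if p.class_label == class_label]
        if rep is not None:
            out = [p for p in out if p.rep == rep]
        return list(out)

    def counts(self) -> dict:
        return dict(Counter((p.scope, p.class_label) for p in self.profiles))

    def n_class_specific(self) -> int:
        """All non-generic profiles: leave-one-out plus class-level pairs."""
        return sum(1 for p in self.profiles if p.scope != "generic")

    def scoring_profiles(self) -> list:
        """Profiles that populate score-table columns (non-generic)."""
        return [p for p in self.profiles if p.scope != "generic"]

    def validate_structure(self, n_per_class: Mapping[str, int]) -> None:
        """Check the canonical registry shape for given training counts."""
        c = self.counts()
        if c.get(("generic", "X"), 0) != 2:
            raise RegistryError("expected 2 generic profiles")
        for cls in CLASSES:
            if c.get(("class", cls), 0) != 2:
                raise RegistryError(f"expected 2 class-level profiles for {cls}")
            expect = 2 * n_per_class[cls]
            if c.get(("loocv", cls), 0) != expect:
                raise RegistryError(
                    f"expected {expect} loocv profiles for class {cls}, got {c.get(('loocv', cls), 0)}")
            uids_1d = {p.excluded_uid for p in self.select("loocv", cls, "1D")}
            uids_3d = {p.excluded_uid for p in self.select("loocv", cls, "3D")}
            if uids_1d != uids_3d:
                raise RegistryError(f"unpaired loocv profiles in class {cls}")

    @classmethod
    def from_training_counts(cls, n_a: int, n_b: int, n_c: int,
                             uids: Optional[Mapping[str, Sequence[str]]] = None) -> "ProfileRegistry":
        """Metadata-only registry with the canonical shape.

        Useful for selection arithmetic (retained-profile counts, delta
        fractions) without building any HMMs.  ``uids`` may supply real
        accessions per class; otherwise placeholders are generated.
        """
        n = {"A": n_a, "B": n_b, "C": n_c}
        profiles = [ProfileHMM(f"gen-{rep.lower()}", "generic", "X", rep) for rep in REPS]
        for c in CLASSES:
            if n[c] < 2:
                raise RegistryError(f"class {c} needs >= 2 training sequences for leave-one-out")
            for rep in REPS:
                profiles.append(ProfileHMM(f"cls-{c}-{rep.lower()}", "class", c, rep))
            class_uids = list(uids[c]) if uids else [f"{c}{i + 1:02d}" for i in range(n[c])]
            if len(class_uids) != n[c]:
                raise RegistryError(f"uids for class {c} do not match count {n[c]}")
            for uid in class_uids:
                for rep in REPS:
                    profiles.append(ProfileHMM(f"loo-{c}-{uid}-{rep.lower()}", "loocv", c, rep,
                                               excluded_uid=uid))
        return cls(profiles)


# ---------------------------------------------------------------------------
# HMM engine plumbing (pyhmmer)

_ALPHABET = pyhmmer.easel.Alphabet.amino()


def _as_text_msa(rows: Sequence, name: bytes = b"msa") -> pyhmmer.easel.TextMSA:
    if len(rows) < 2:
        raise AlignmentError("alignment needs at least 2 rows")
    seqs = []
    width = None
    for rid, aligned in rows:
        if width is None:
            width = len(aligned)
        elif len(aligned) != width:
            raise AlignmentError(f"ragged alignment: row {rid} has length {len(aligned)} != {width}")
        seqs.append(pyhmmer.easel.TextSequence(name=str(rid).encode(), sequence=str(aligned)))
    if not width:
        raise AlignmentError("empty alignment")
    return pyhmmer.easel.TextMSA(name=name, sequences=seqs)


def build_profile(alignment: Sequence, profile_id: str, scope: str, class_label: str,
                  rep: str, excluded_uid: Optional[str] = None) -> ProfileHMM:
    """Build one profile HMM from an alignment (rows of ``(id, aligned_seq)``).

    Model construction is delegated to the HMMER implementation (pyhmmer);
    the returned profile records the supplied metadata verbatim and the
    match-state count of the compiled model.
    """
    msa = _as_text_msa(alignment, name=profile_id.encode())
    try:
        digital = msa.digitize(_ALPHABET)
        builder = pyhmmer.plan7.Builder(_ALPHABET)
        background = pyhmmer.plan7.Background(_ALPHABET)
        hmm, _, _ = builder.build_msa(digital, background)
    except AlignmentError:
        raise
    except Exception as exc:  # pragma: no cover - engine failure path
        raise RuntimeError(f"HMM engine failed building {profile_id}: {exc}") from exc
    return ProfileHMM(profile_id, scope, class_label, rep, excluded_uid=excluded_uid,
                      model_length=hmm.M, hmm=hmm)


def _subset_alignment(rows: Sequence, drop_uid: str) -> list:
    """Remove one row and any columns left gap-only."""
    kept = [(rid, s) for rid, s in rows if rid != drop_uid]
    if len(kept) == len(rows):
        raise KeyError(f"{drop_uid} not in alignment")
    cols = [i for i in range(len(kept[0][1]))
            if any(s[i] not in "-." for _, s in kept)]
    return [(rid, "".join(s[i] for i in cols)) for rid, s in kept]


def build_loocv_registry(training: Sequence, msa_1d: Sequence, msa_3d: Sequence) -> ProfileRegistry:
    """Build the full registry from a training set and two full alignments.

    ``msa_1d``/``msa_3d`` are full-training-set alignments as rows of
    ``(uid, aligned_seq)`` whose ids cover every training sequence.  Class
    and leave-one-out alignments are derived by row subsetting (dropping
    columns that become all-gap), which keeps the two representations in
    lock-step: every leave-one-out 1D profile has a 3D partner excluding
    the same accession.
    """
    by_class: dict = {c: [t for t in training if t.class_label == c] for c in CLASSES}
    for c, members in by_class.items():
        if len(members) < 2:
            raise RegistryError(f"class {c} has {len(members)} sequences; leave-one-out undefined")
    msas = {"1D": list(msa_1d), "3D": list(msa_3d)}
    ids = {rep: {rid for rid, _ in rows} for rep, rows in msas.items()}
    for t in training:
        for rep in REPS:
            if t.uid not in ids[rep]:
                raise RegistryError(f"training sequence {t.uid} missing from the {rep} alignment")

    profiles = []
    for rep in REPS:
        profiles.append(build_profile(msas[rep], f"gen-{rep.lower()}", "generic", "X", rep))
    for c in CLASSES:
        uids = {t.uid for t in by_class[c]}
        for rep in REPS:
            class_rows = [(rid, s) for rid, s in msas[rep] if rid in uids]
            class_rows = _strip_gap_columns(class_rows)
            profiles.append(build_profile(class_rows, f"cls-{c}-{rep.lower()}", "class", c, rep))
            for t in by_class[c]:
                sub = _subset_alignment(class_rows, t.uid)
                profiles.append(build_profile(
                    sub, f"loo-{c}-{t.uid}-{rep.lower()}", "loocv", c, rep, excluded_uid=t.uid))
    registry = ProfileRegistry(profiles)
    registry.validate_structure({c: len(by_class[c]) for c in CLASSES})
    return registry


def _strip_gap_columns(rows: list) -> list:
    cols = [i for i in range(len(rows[0][1])) if any(s[i] not in "-." for _, s in rows)]
    return [(rid, "".join(s[i] for i in cols)) for rid, s in rows]


def _digital_block(seqs: Mapping[str, str]) -> pyhmmer.easel.DigitalSequenceBlock:
    texts = [pyhmmer.easel.TextSequence(name=sid.encode(), sequence=res)
             for sid, res in seqs.items()]
    return pyhmmer.easel.DigitalSequenceBlock(_ALPHABET, [t.digitize(_ALPHABET) for t in texts])


def _search(profile: ProfileHMM, block, evalue: float) -> dict:
    """Best-region bit score per hit id at sequence E-value <= ``evalue``."""
    if profile.hmm is None:
        raise RegistryError(f"profile {profile.profile_id} carries no compiled model")
    background = pyhmmer.plan7.Background(_ALPHABET)
    pipeline = pyhmmer.plan7.Pipeline(_ALPHABET, background=background,
                                      E=evalue, domE=evalue)
    hits = pipeline.search_hmm(profile.hmm, block)
    out = {}
    for hit in hits:
        if hit.evalue > evalue:
            continue
        name = hit.name
        out[name.decode() if isinstance(name, bytes) else str(name)] = hit
    return out


def screen_homologs(seqs: Mapping[str, str], registry: ProfileRegistry,
                    cfg: SearchConfig) -> set:
    """Ids hit by either generic profile at the permissive threshold."""
    generic = registry.select(scope="generic")
    if not generic:
        raise RegistryError("registry has no generic profiles")
    if not seqs:
        return set()
    block = _digital_block(seqs)
    found: set = set()
    for profile in generic:
        found.update(_search(profile, block, cfg.e_generic).keys())
    return found


def score_profiles(seqs: Mapping[str, str], registry: ProfileRegistry,
                   cfg: Optional[SearchConfig] = None) -> pd.DataFrame:
    """Score table: rows = sequence ids, columns = class/loocv profile ids.

    Each cell is the best single-region bit score of that sequence against
    that profile (or the full-sequence score under
    ``cfg.score_kind="sequence"``); NaN marks profiles with no hit at the
    reporting threshold.
    """
    cfg = cfg or SearchConfig()
    cols = registry.scoring_profiles()
    if not cols:
        raise RegistryError("registry has no class or loocv profiles")
    table = pd.DataFrame(np.nan, index=list(seqs.keys()),
                         columns=[p.profile_id for p in cols], dtype=float)
    if not seqs:
        return table
    block = _digital_block(seqs)
    for profile in cols:
        for sid, hit in _search(profile, block, cfg.e_class).items():
            if cfg.score_kind == "sequence":
                table.at[sid, profile.profile_id] = float(hit.score)
            else:
                table.at[sid, profile.profile_id] = float(
                    max(d.score for d in hit.domains))
    return table


def select_loocv(target_uid: str, target_class: str, registry: ProfileRegistry) -> LoocvSelection:
    """Apply the leave-one-out profile selection rule for a training sequence.

    Retained: every leave-one-out profile of the two other classes plus the
    single (1D, 3D) pair of the target's class built without the target.
    """
    if target_class not in CLASSES:
        raise ValueError(f"bad class {target_class!r}")
    own_pair = [p for p in registry.select("loocv", target_class)
                if p.excluded_uid == target_uid]
    if len(own_pair) != 2:
        raise KeyError(f"no (1D,3D) leave-one-out pair excluding {target_uid} "
                       f"in class {target_class}")
    others = [p for p in registry.select("loocv") if p.class_label != target_class]
    retained = tuple(sorted(p.profile_id for p in own_pair + others))
    total = registry.n_class_specific()
    return LoocvSelection(target_uid, target_class, retained, len(retained) / total)


def class_means(row: pd.Series, registry: ProfileRegistry, mode: str = "generic",
                selection: Optional[LoocvSelection] = None) -> ClassMeanTriple:
    """Reduce one score-table row to per-class mean scores.

    Generic mode averages each class's (1D, 3D) class-level pair; loocv mode
    averages over the retained profiles of each class.  Missing cells are
    zeroed with a warning when the class still has at least one real hit;
    a class with no hits at all makes the sequence unclassifiable.
    """
    if mode not in ("generic", "loocv"):
        raise ValueError(f"bad mode {mode!r}")
    if mode == "loocv" and selection is None:
        raise ValueError("loocv mode requires a LoocvSelection")
    means = {}
    contributing = {}
    side_means = {}
    for cls in CLASSES:
        if mode == "generic":
            prof = registry.select(scope="class", class_label=cls)
        else:
            prof = [p for p in registry.select(scope="loocv", class_label=cls)
                    if p.profile_id in selection.retained_profile_ids]
        ids = sorted(p.profile_id for p in prof)
        if not ids:
            raise DegenerateScoreError(f"no profiles selected for class {cls}")
        vals = row.reindex(ids)
        if vals.isna().all():
            raise DegenerateScoreError(
                f"sequence {row.name!r} has no hit for any class-{cls} profile")
        if vals.isna().any():
            warnings.warn(f"sequence {row.name!r}: missing scores for "
                          f"{sorted(vals.index[vals.isna()])} treated as 0 bits",
                          stacklevel=2)
            vals = vals.fillna(0.0)
        means[cls] = float(vals.mean())
        contributing[cls] = tuple(ids)
        by_rep = {rep: [p.profile_id for p in prof if p.rep == rep] for rep in REPS}
        side_means[cls] = tuple(
            float(vals.reindex(by_rep[rep]).mean()) if by_rep[rep] else means[cls]
            for rep in REPS)
    return ClassMeanTriple(means["A"], means["B"], means["C"], mode,
                           contributing, side_means)


def max_class(triple: ClassMeanTriple) -> MaxClassResult:
    """Class of the strictly largest mean score; ties flag ambiguity."""
    d = triple.as_dict()
    top = max(d.values())
    winners = [c for c in CLASSES if d[c] == top]
    if len(winners) > 1:
        return MaxClassResult(None, True)
    return MaxClassResult(winners[0], False)
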