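"""Long-format nested datasets: containers, validation, I/O and fixtures.

Laboratory data with a subject / sample / replicate hierarchy are held in a
:class:`NestedDataset`, a thin validated wrapper around a long-format
:class:`pandas.DataFrame`.  Treatment (the ``group`` column) is applied at the
subject level — the subject is the experimental unit — while observations may
sit one or two strata below it.  Sample and replicate identifiers are nested
labels: sample "1" of subject 1 is a different physical sample from sample "1"
of subject 2, so internal keys are always (subject, sample) pairs.

Two fixtures from a colorectal-cancer radiotherapy study ship with the
package: ``lymph_size`` (72 lymph-node diameters, mm; 12 subjects x 2 tissue
samples x 3 slices) and ``lymph_count`` (counts of nodes >= 2 mm out of 5
inspected, for up to 5 samples per subject).  See ``data/MANIFEST.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "NestedDataset",
    "DesignLayout",
    "read_long_csv",
    "write_long_csv",
    "load_fixture",
    "remove_fraction",
    "FIXTURES",
]

OutcomeKind = Literal["continuous", "binomial"]

#: canonical column order for continuous / binomial outcomes
_CONT_COLS = ["group", "subject", "sample", "replicate", "value"]
_BIN_COLS = ["group", "subject", "sample", "replicate", "events", "trials"]

#: markers in printed tables meaning "no observation taken"
MISSING_MARKERS = {"-", "", "NA", "na", None}

FIXTURES = ("lymph_size", "lymph_count")


@dataclass(frozen=True)
class NestedDataset:
    """A validated long-format dataset with nested grouping labels.

    Parameters
    ----------
    frame
        Long-format table.  Continuous outcomes need columns
        ``group, subject, sample, replicate, value``; binomial outcomes need
        ``group, subject, sample, events, trials``.  ``sample`` and
        ``replicate`` may be absent (single-stratum data) and are stored as
        empty strings internally.
    outcome_kind
        ``"continuous"`` or ``"binomial"``; the two are mutually exclusive.
    """

    frame: pd.DataFrame
    outcome_kind: OutcomeKind = "continuous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", _normalise(self.frame, self.outcome_kind))
        _validate(self.frame, self.outcome_kind)

    # -- basic queries -----------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique(), key=_natural_key)

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    @property
    def group_of_subject(self) -> dict[str, str]:
        return dict(
            self.frame.drop_duplicates("subject")[["subject", "group"]].itertuples(
                index=False, name=None
            )
        )

    @property
    def is_balanced(self) -> bool:
        """True when every subject has the same number of samples and every
        sample the same number of records."""
        per_subject = self.frame.groupby("subject", observed=True)["sample"].nunique()
        per_sample = self.frame.groupby(["subject", "sample"], observed=True).size()
        return per_subject.nunique() == 1 and per_sample.nunique() == 1

    def strata_counts(self) -> dict[str, int]:
        """Observation counts at each stratum of the hierarchy."""
        out = {
            "group": self.frame["group"].nunique(),
            "subject": self.frame["subject"].nunique(),
            "sample": len(self.frame.drop_duplicates(["subject", "sample"])),
            "record": len(self.frame),
        }
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NestedDataset):
            return NotImplemented
        if self.outcome_kind != other.outcome_kind:
            return False
        a = self.frame.sort_values(list(self.frame.columns)).reset_index(drop=True)
        b = other.frame.sort_values(list(other.frame.columns)).reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class DesignLayout:
    """A balanced nested design: groups / subjects / samples / replicates."""

    n_groups: int = 2
    subjects_per_group: int = 6
    samples_per_subject: int = 2
    replicates_per_sample: int = 3

    def __post_init__(self) -> None:
        for name in (
            "n_groups",
            "subjects_per_group",
            "samples_per_subject",
            "replicates_per_sample",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValidationError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def n_subjects(self) -> int:
        return self.n_groups * self.subjects_per_group

    @property
    def n_samples(self) -> int:
        return self.n_subjects * self.samples_per_subject

    @property
    def n_observations(self) -> int:
        return self.n_samples * self.replicates_per_sample


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _natural_key(s: str):
    return (0, int(s)) if str(s).isdigit() else (1, str(s))


def _normalise(frame: pd.DataFrame, outcome_kind: OutcomeKind) -> pd.DataFrame:
    cols = _CONT_COLS if outcome_kind == "continuous" else _BIN_COLS
    df = frame.copy()
    for c in ("sample", "replicate"):
        if c not in df.columns:
            df[c] = ""
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df[cols]
    for c in ("group", "subject", "sample", "replicate"):
        df[c] = df[c].astype(str).str.strip()
    if outcome_kind == "continuous":
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
    else:
        for c in ("events", "trials"):
            df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame, outcome_kind: OutcomeKind) -> None:
    if df.empty:
        raise ValidationError("dataset contains no records")
    n_groups_per_subject = df.groupby("subject", observed=True)["group"].nunique()
    bad = n_groups_per_subject[n_groups_per_subject > 1]
    if len(bad):
        raise ValidationError(
            f"subjects assigned to more than one group: {list(bad.index)} "
            "(treatment is applied at the subject level)"
        )
    dup = df.duplicated(["subject", "sample", "replicate"])
    if dup.any():
        rows = df.loc[dup, ["subject", "sample", "replicate"]].values.tolist()
        raise ValidationError(f"duplicate (subject, sample, replicate) keys: {rows[:5]}")
    if outcome_kind == "binomial":
        if (df["trials"] <= 0).any():
            raise ValidationError("binomial trials must be positive")
        if ((df["events"] < 0) | (df["events"] > df["trials"])).any():
            raise ValidationError("binomial events must satisfy 0 <= events <= trials")
    else:
        if df["value"].isna().any():
            raise ValidationError("continuous outcome contains missing values")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_long_csv(
    path,
    schema: Mapping[str, str] | None = None,
    outcome_kind: OutcomeKind = "continuous",
    tsv: bool = False,
) -> NestedDataset:
    """Read a long-format CSV/TSV into a validated :class:`NestedDataset`.

    Parameters
    ----------
    path
        File path (UTF-8, header row required).
    schema
        Optional mapping from canonical names (``group``, ``subject``,
        ``sample``, ``replicate``, ``value`` | ``events``, ``trials``) to the
        column names used in the file.
    outcome_kind
        Outcome type; selects the required value columns.
    tsv
        Read tab-separated instead of comma-separated input.

    Records whose outcome cell holds a missing marker (``-`` or empty) are
    dropped, supporting unbalanced printed tables where absent cells mean
    "no observation", not zero.
    """
    sep = "\t" if tsv else ","
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty input file: {path}") from exc
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing = [v for v in schema.values() if v not in raw.columns]
        if missing:
            raise ValidationError(f"mapped columns absent from file: {missing}")
        raw = raw.rename(columns=rename)
    value_cols = ["value"] if outcome_kind == "continuous" else ["events", "trials"]
    for c in value_cols:
        if c not in raw.columns:
            raise ValidationError(f"required column {c!r} not found in {path}")
    keep = ~raw[value_cols].isin(MISSING_MARKERS).any(axis=1)
    raw = raw.loc[keep]
    return NestedDataset(raw, outcome_kind=outcome_kind)


def write_long_csv(data: NestedDataset, path, tsv: bool = False) -> None:
    """Write a dataset back to long-format CSV/TSV (round-trips with
    :func:`read_long_csv`)."""
    sep = "\t" if tsv else ","
    data.frame.to_csv(path, sep=sep, index=False)


def load_fixture(name: str) -> NestedDataset:
    """Load a packaged example dataset.

    ``"lymph_size"``
        72 lymph-node diameters (mm): 2 radiotherapy groups x 6 subjects x
        2 tissue samples x 3 slices, fully balanced.
    ``"lymph_count"``
        50 binomial records: number of 5 inspected lymph nodes with diameter
        >= 2 mm per tissue sample, up to 5 samples per subject (unbalanced).
    """
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; available: {FIXTURES}")
    kind: OutcomeKind = "continuous" if name == "lymph_size" else "binomial"
    with resources.files("uoastats.data").joinpath(f"{name}.csv").open("rb") as fh:
        return read_long_csv(fh, outcome_kind=kind)


# ---------------------------------------------------------------------------
# unbalancing
# ---------------------------------------------------------------------------

def remove_fraction(data: NestedDataset, fraction: float, seed) -> NestedDataset:
    """Randomly delete a fraction of records, keeping >= 1 record per subject.

    Used to study unbalanced re-analyses: records are removed uniformly at
    random, except that a removal that would empty a subject is skipped (the
    subject must stay in the study).  Deterministic given ``seed``.
    """
    if not 0 <= fraction < 1:
        raise ValidationError(f"fraction must be in [0, 1), got {fraction}")
    n = data.n_records
    n_remove = int(round(fraction * n))
    if n_remove == 0:
        return data
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    counts = data.frame.groupby("subject", observed=True).size().to_dict()
    drop: list[int] = []
    for idx in order:
        if len(drop) == n_remove:
            break
        subj = data.frame.iloc[idx]["subject"]
        if counts[subj] > 1:
            counts[subj] -= 1
            drop.append(idx)
    if len(drop) < n_remove:
        raise ValidationError(
            f"cannot remove {n_remove} records while keeping one per subject"
        )
    kept = data.frame.drop(index=data.frame.index[drop])
    return NestedDataset(kept, outcome_kind=data.outcome_kind)
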