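"""Data model and file I/O for meta-epidemiological datasets.

A dataset is a flat table of trials.  Each trial belongs to one
meta-analysis and carries event counts and sample sizes for a control and a
treatment arm, plus one 0/1 indicator per binary study characteristic
(``X_ijm`` for trial ``i``, characteristic ``j``, meta-analysis ``m``).

The on-disk format is plain CSV with columns ``meta_id, trial_id,
events_control, n_control, events_treat, n_treat`` followed by one 0/1
column per characteristic (the header supplies the characteristic names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "meta_id",
    "trial_id",
    "events_control",
    "n_control",
    "events_treat",
    "n_treat",
)


@dataclass(frozen=True)
class TrialRecord:
    """A single two-arm trial with binary outcome counts.

    ``characteristics`` is the ordered tuple of 0/1 indicators, one per
    study characteristic in the parent dataset.
    """

    meta_id: str
    trial_id: str
    events_control: int
    n_control: int
    events_treat: int
    n_treat: int
    characteristics: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_treat < 1:
            raise ValueError(
                f"trial {self.trial_id!r} in {self.meta_id!r}: arm sizes must be >= 1"
            )
        if not (0 <= self.events_control <= self.n_control):
            raise ValueError(
                f"trial {self.trial_id!r} in {self.meta_id!r}: "
                f"events_control={self.events_control} outside [0, {self.n_control}]"
            )
        if not (0 <= self.events_treat <= self.n_treat):
            raise ValueError(
                f"trial {self.trial_id!r} in {self.meta_id!r}: "
                f"events_treat={self.events_treat} outside [0, {self.n_treat}]"
            )
        if any(x not in (0, 1) for x in self.characteristics):
            raise ValueError(
                f"trial {self.trial_id!r} in {self.meta_id!r}: "
                "characteristic indicators must be 0 or 1"
            )


@dataclass
class MetaEpiDataset:
    """A collection of trials grouped into meta-analyses.

    Parameters
    ----------
    trials
        Sequence of :class:`TrialRecord`; row order is preserved.
    characteristic_names
        Labels for the binary study characteristics; every trial must carry
        exactly this many indicators.
    """

    trials: list[TrialRecord]
    characteristic_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = len(self.characteristic_names)
        for t in self.trials:
            if len(t.characteristics) != p:
                raise ValueError(
                    f"trial {t.trial_id!r} in {t.meta_id!r} has "
                    f"{len(t.characteristics)} characteristic indicators, expected {p}"
                )

    # -- basic views ------------------------------------------------------

    @property
    def n_characteristics(self) -> int:
        return len(self.characteristic_names)

    @property
    def meta_ids(self) -> list[str]:
        """Distinct meta-analysis identifiers, in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.meta_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetaEpiDataset):
            return NotImplemented
        return (
            self.trials == other.trials
            and self.characteristic_names == other.characteristic_names
        )

    def trials_in(self, meta_id: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.meta_id == meta_id]

    def characteristic_index(self, characteristic: int | str) -> int:
        """Resolve a characteristic given by name or 0-based index.

        Raises :class:`IndexError` if the name is unknown or the index is
        out of range.
        """
        if isinstance(characteristic, str):
            try:
                return self.characteristic_names.index(characteristic)
            except ValueError:
                raise IndexError(
                    f"unknown characteristic {characteristic!r}; "
                    f"available: {self.characteristic_names}"
                ) from None
        j = int(characteristic)
        if not 0 <= j < self.n_characteristics:
            raise IndexError(
                f"characteristic index {j} out of range for p={self.n_characteristics}"
            )
        return j

    # -- tabular conversion ----------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.meta_id, t.trial_id, t.events_control, t.n_control, t.events_treat, t.n_treat)
            + t.characteristics
            for t in self.trials
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + self.characteristic_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, characteristic_names: Sequence[str]) -> "MetaEpiDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        missing = [c for c in characteristic_names if c not in df.columns]
        if missing:
            raise ValueError(f"missing characteristic column(s): {missing}")
        trials = []
        for idx, row in df.iterrows():
            chars = []
            for name in characteristic_names:
                v = row[name]
                if v not in (0, 1):
                    raise ValueError(
                        f"row {idx}: characteristic {name!r} has non-binary value {v!r}"
                    )
                chars.append(int(v))
            try:
                trials.append(
                    TrialRecord(
                        meta_id=str(row["meta_id"]),
                        trial_id=str(row["trial_id"]),
                        events_control=int(row["events_control"]),
                        n_control=int(row["n_control"]),
                        events_treat=int(row["events_treat"]),
                        n_treat=int(row["n_treat"]),
                        characteristics=tuple(chars),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"row {idx}: {exc}") from None
        return cls(trials=trials, characteristic_names=list(characteristic_names))

    # -- array views for the sampler -------------------------------------

    def arrays(self) -> dict[str, np.ndarray]:
        """Column arrays plus a 0-based meta-analysis index per trial."""
        df = self.to_frame()
        meta_ids = self.meta_ids
        meta_index = {mid: k for k, mid in enumerate(meta_ids)}
        return {
            "events_control": df["events_control"].to_numpy(dtype=np.int64),
            "n_control": df["n_control"].to_numpy(dtype=np.int64),
            "events_treat": df["events_treat"].to_numpy(dtype=np.int64),
            "n_treat": df["n_treat"].to_numpy(dtype=np.int64),
            "X": df[self.characteristic_names].to_numpy(dtype=np.float64)
            if self.characteristic_names
            else np.zeros((len(df), 0)),
            "meta_index": np.array([meta_index[t.meta_id] for t in self.trials], dtype=np.int64),
        }


@dataclass
class InformativenessFlags:
    """Which meta-analyses can inform estimation for one characteristic.

    A meta-analysis is *informative for the mean* difference if it contains
    at least one trial with and one without the characteristic, and
    *informative for the variance* inflation (kappa^2 or lambda) if it
    contains at least two trials in each category.  Variance-informative
    implies mean-informative.
    """

    characteristic: str
    informative_for_mean: dict[str, bool]
    informative_for_variance: dict[str, bool]

    def __post_init__(self) -> None:
        for mid, var_ok in self.informative_for_variance.items():
            if var_ok and not self.informative_for_mean[mid]:
                raise ValueError(f"meta {mid!r}: variance-informative but not mean-informative")


def classify_informative(dataset: MetaEpiDataset, characteristic: int | str) -> InformativenessFlags:
    """Classify every meta-analysis as informative or not for one characteristic.

    ``characteristic`` may be a name from ``dataset.characteristic_names``
    or a 0-based index.
    """
    j = dataset.characteristic_index(characteristic)
    mean_flags: dict[str, bool] = {}
    var_flags: dict[str, bool] = {}
    for mid in dataset.meta_ids:
        xs = [t.characteristics[j] for t in dataset.trials_in(mid)]
        n1 = sum(xs)
        n0 = len(xs) - n1
        mean_flags[mid] = n1 >= 1 and n0 >= 1
        var_flags[mid] = n1 >= 2 and n0 >= 2
    return InformativenessFlags(
        characteristic=dataset.characteristic_names[j],
        informative_for_mean=mean_flags,
        informative_for_variance=var_flags,
    )


def relabel(dataset: MetaEpiDataset, characteristic: int | str) -> MetaEpiDataset:
    """Swap the two categories of one characteristic (0 <-> 1) in every trial.

    Used to verify label-invariance: under the multiplicative variance
    structure, refitting after relabelling maps ``b0 -> -b0`` and
    ``lambda -> 1/lambda``.
    """
    j = dataset.characteristic_index(characteristic)
    trials = [
        TrialRecord(
            meta_id=t.meta_id,
            trial_id=t.trial_id,
            events_control=t.events_control,
            n_control=t.n_control,
            events_treat=t.events_treat,
            n_treat=t.n_treat,
            characteristics=tuple(
                1 - x if k == j else x for k, x in enumerate(t.characteristics)
            ),
        )
        for t in dataset.trials
    ]
    return MetaEpiDataset(trials=trials, characteristic_names=list(dataset.characteristic_names))


def small_trial_indicator(
    dataset: MetaEpiDataset, threshold: int = 100, name: str = "small_trial"
) -> MetaEpiDataset:
    """Append a characteristic flagging trials with fewer than ``threshold``
    total analysed participants (``n_control + n_treat``, strict inequality).
    """
    trials = [
        TrialRecord(
            meta_id=t.meta_id,
            trial_id=t.trial_id,
            events_control=t.events_control,
            n_control=t.n_control,
            events_treat=t.events_treat,
            n_treat=t.n_treat,
            characteristics=t.characteristics
            + (1 if t.n_control + t.n_treat < threshold else 0,),
        )
        for t in dataset.trials
    ]
    return MetaEpiDataset(
        trials=trials, characteristic_names=list(dataset.characteristic_names) + [name]
    )


def load_dataset(path: str | Path, p: int | None = None) -> MetaEpiDataset:
    """Read a dataset from CSV.

    Characteristic columns are every column after the six required ones, in
    header order.  If ``p`` is given, the file must contain exactly ``p``
    characteristic columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    char_names = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if p is not None and len(char_names) != p:
        raise ValueError(
            f"{path}: expected {p} characteristic column(s), found {len(char_names)}: {char_names}"
        )
    return MetaEpiDataset.from_frame(df, char_names)


def write_dataset(dataset: MetaEpiDataset, path: str | Path) -> None:
    """Write a dataset to CSV (UTF-8, comma-separated, header row)."""
    dataset.to_frame().to_csv(path, index=False)
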