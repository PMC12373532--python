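"""The 27-item monetary-choice instrument: items, banks and choice-data I/O.

The instrument is a fixed ladder of binary questions of the form "would you
prefer $A today, or $B in D days?" with B > A.  Each item is characterised by
its *indifference discount rate*: the hyperbolic rate k at which the two
options have equal discounted value,

    A = B / (1 + k * D)   =>   k = (B / A - 1) / D.

A respondent with a hyperbolic discount rate above an item's indifference rate
prefers the immediate option on that item; the ladder of indifference rates is
what makes the individual rate identifiable from 27 binary answers.

The canonical published 27-item bank (Kirby, Petry & Bickel, 1999) ships with
the package as a CSV fixture and is available through :meth:`ItemBank.kirby27`.
Amounts are treated as unit-agnostic internally; the canonical bank is
denominated in USD.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IMMEDIATE",
    "DELAYED",
    "CHOICE_LABELS",
    "ValidationError",
    "ChoiceItem",
    "ItemBank",
    "ChoiceDataset",
    "BankReport",
    "item_indifference_k",
    "validate_item_bank",
    "load_choice_data",
    "write_choice_data",
]

#: On-disk / user-facing labels for the two options.  Internally an immediate
#: choice is encoded as 1 and a delayed choice as 0.
IMMEDIATE = "immediate"
DELAYED = "delayed"
CHOICE_LABELS = (IMMEDIATE, DELAYED)


class ValidationError(ValueError):
    """Raised when input data violate the instrument's contracts."""


@dataclass(frozen=True)
class ChoiceItem:
    """One instrument row: an immediate amount versus a larger delayed amount.

    Parameters
    ----------
    item_id : int
        Identifier, unique within a bank.
    immediate_amount : float
        Amount of the smaller-sooner option (currency units, > 0).
    delayed_amount : float
        Amount of the larger-later option (currency units, > 0).
    delay_days : int
        Delay of the later option in days (>= 1).
    """

    item_id: int
    immediate_amount: float
    delayed_amount: float
    delay_days: int

    def __post_init__(self) -> None:
        if self.immediate_amount <= 0 or self.delayed_amount <= 0:
            raise ValidationError(
                f"item {self.item_id}: amounts must be positive, got "
                f"({self.immediate_amount}, {self.delayed_amount})"
            )
        if self.delay_days < 1:
            raise ValidationError(
                f"item {self.item_id}: delay_days must be >= 1, got {self.delay_days}"
            )


def item_indifference_k(item: ChoiceItem) -> float:
    """Hyperbolic discount rate (1/day) at which the item's options tie.

    Solves ``immediate = delayed / (1 + k * delay)`` for k, giving
    ``(delayed/immediate - 1) / delay``.  Strictly positive for any valid
    item; an item whose delayed amount does not exceed its immediate amount
    carries no information about the discount rate and raises.
    """
    if item.delayed_amount <= item.immediate_amount:
        raise ValidationError(
            f"item {item.item_id}: delayed amount ({item.delayed_amount}) must "
            f"exceed immediate amount ({item.immediate_amount}); item is uninformative"
        )
    return (item.delayed_amount / item.immediate_amount - 1.0) / item.delay_days


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of :class:`ChoiceItem` with unique ids."""

    items: tuple[ChoiceItem, ...]
    _by_id: Mapping[int, ChoiceItem] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if not items:
            raise ValidationError("item bank is empty")
        ids = [it.item_id for it in items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate item_id in bank: {sorted(dupes)}")
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "_by_id", {it.item_id: it for it in items})

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ChoiceItem]:
        return iter(self.items)

    def __getitem__(self, item_id: int) -> ChoiceItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"item_id {item_id} not in bank") from None

    def __contains__(self, item_id: int) -> bool:
        return item_id in self._by_id

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(it.item_id for it in self.items)

    def indifference_rates(self) -> np.ndarray:
        """Indifference k of every item, in bank order."""
        return np.array([item_indifference_k(it) for it in self.items])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "immediate_amount": [it.immediate_amount for it in self.items],
                "delayed_amount": [it.delayed_amount for it in self.items],
                "delay_days": [it.delay_days for it in self.items],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ItemBank":
        required = {"item_id", "immediate_amount", "delayed_amount", "delay_days"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"item bank is missing columns: {sorted(missing)}")
        items = tuple(
            ChoiceItem(
                item_id=int(r.item_id),
                immediate_amount=float(r.immediate_amount),
                delayed_amount=float(r.delayed_amount),
                delay_days=int(r.delay_days),
            )
            for r in frame.itertuples()
        )
        return cls(items)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def kirby27(cls) -> "ItemBank":
        """The canonical published 27-item monetary-choice bank.

        Sourced from the original instrument (Kirby, Petry & Bickel, 1999);
        indifference rates span roughly 1.6e-4 to 0.25 per day in a 3 x 9
        ladder of magnitudes and rates.
        """
        ref = importlib.resources.files("hyperdisc.data") / "kirby27.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)


@dataclass(frozen=True)
class ChoiceDataset:
    """One participant-timepoint's binary answers over an item bank.

    ``choices`` maps item_id to one of the labels ``"immediate"`` /
    ``"delayed"``.
    """

    participant_id: str
    timepoint: int
    choices: Mapping[int, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.choices.values() if v not in CHOICE_LABELS}
        if bad:
            raise ValidationError(
                f"participant {self.participant_id}: unknown choice labels {sorted(bad)}; "
                f"expected one of {CHOICE_LABELS}"
            )
        if not self.choices:
            raise ValidationError(f"participant {self.participant_id}: no choices")

    def __len__(self) -> int:
        return len(self.choices)

    def validate_against(self, bank: ItemBank) -> None:
        unknown = [i for i in self.choices if i not in bank]
        if unknown:
            raise ValidationError(
                f"participant {self.participant_id}: item ids {unknown} not in bank"
            )

    def immediate_indicator(self, bank: ItemBank) -> np.ndarray:
        """0/1 vector (1 = chose immediate), ordered by item_id."""
        self.validate_against(bank)
        ids = sorted(self.choices)
        return np.array([1 if self.choices[i] == IMMEDIATE else 0 for i in ids])

    def item_ids(self) -> list[int]:
        return sorted(self.choices)


@dataclass(frozen=True)
class BankReport:
    """Validation summary for an item bank (see :func:`validate_item_bank`)."""

    n_items: int
    k_min: float
    k_max: float
    fit_bounds: tuple[float, float]
    #: nominal sensitive range quoted for the published instrument
    nominal_range: tuple[float, float]
    flags: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_item_bank(
    bank: ItemBank,
    k_bounds: tuple[float, float] = (1e-4, 0.25),
    nominal_range: tuple[float, float] = (1e-5, 1.0),
) -> BankReport:
    """Report the bank's indifference-rate range against the fit bounds.

    A bank is flagged when its indifference rates do not come within a factor
    of 10 of each fit bound (the fitted rate is then poorly identified near
    that bound), or when it contains a single item (the rate is identifiable
    only as above/below one threshold).  The instrument's nominal sensitive
    range and the fit bounds are both echoed in the report; they need not
    agree.
    """
    ks = bank.indifference_rates()
    k_min, k_max = float(ks.min()), float(ks.max())
    flags: list[str] = []
    if len(bank) == 1:
        flags.append(
            "single-item bank: k identifiable only as above/below one threshold"
        )
    if k_min > k_bounds[0] * 10:
        flags.append(
            f"smallest indifference k ({k_min:.3g}) is more than 10x the lower "
            f"fit bound ({k_bounds[0]:g}); small rates poorly identified"
        )
    if k_max < k_bounds[1] / 10:
        flags.append(
            f"largest indifference k ({k_max:.3g}) is less than 1/10 of the upper "
            f"fit bound ({k_bounds[1]:g}); large rates poorly identified"
        )
    if k_min > 0 and k_max / k_min < 100:
        flags.append(
            "indifference rates span less than two orders of magnitude; "
            "rate poorly identifiable"
        )
    return BankReport(
        n_items=len(bank),
        k_min=k_min,
        k_max=k_max,
        fit_bounds=k_bounds,
        nominal_range=nominal_range,
        flags=tuple(flags),
    )


_CHOICE_COLUMNS = ["participant_id", "timepoint", "item_id", "choice"]


def load_choice_data(path: str | Path, bank: ItemBank) -> list[ChoiceDataset]:
    """Read long-format choice data and validate it against a bank.

    The CSV must have columns ``participant_id, timepoint, item_id, choice``
    with choice labels ``immediate`` / ``delayed``.  Returns one
    :class:`ChoiceDataset` per (participant, timepoint), in file order.

    Raises
    ------
    ValidationError
        On unknown item ids (naming the offending row), duplicate
        (participant, timepoint, item) triples, or unknown choice labels.
    """
    df = pd.read_csv(path)
    missing = set(_CHOICE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    bad_label = ~df["choice"].isin(CHOICE_LABELS)
    if bad_label.any():
        row = df.index[bad_label][0]
        raise ValidationError(
            f"{path}: row {row + 2}: unknown choice label {df.loc[row, 'choice']!r}"
        )
    bad_item = ~df["item_id"].isin(bank.item_ids)
    if bad_item.any():
        row = df.index[bad_item][0]
        raise ValidationError(
            f"{path}: row {row + 2}: item_id {df.loc[row, 'item_id']} not in bank"
        )
    dupes = df.duplicated(subset=["participant_id", "timepoint", "item_id"])
    if dupes.any():
        row = df.index[dupes][0]
        raise ValidationError(
            f"{path}: row {row + 2}: duplicate response for participant "
            f"{df.loc[row, 'participant_id']!r}, timepoint {df.loc[row, 'timepoint']}, "
            f"item {df.loc[row, 'item_id']}"
        )

    datasets = []
    for (pid, tp), grp in df.groupby(["participant_id", "timepoint"], sort=False):
        datasets.append(
            ChoiceDataset(
                participant_id=str(pid),
                timepoint=int(tp),
                choices={int(r.item_id): str(r.choice) for r in grp.itertuples()},
            )
        )
    return datasets


def write_choice_data(datasets: Sequence[ChoiceDataset], path: str | Path) -> None:
    """Write datasets in the long CSV format read by :func:`load_choice_data`."""
    rows = [
        (ds.participant_id, ds.timepoint, item_id, ds.choices[item_id])
        for ds in datasets
        for item_id in sorted(ds.choices)
    ]
    pd.DataFrame(rows, columns=_CHOICE_COLUMNS).to_csv(path, index=False)
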