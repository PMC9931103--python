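"""Instrument battery data model and score tables.

A *battery* is the ordered set of psychometric items that become the nodes
of a symptom network.  The default battery bundles 17 items from three
domains: nine neurocognitive test scores, two affective (depression
severity) scales, and the six psychosocial functioning domains of the FAST.

Score tables hold one row per subject and one column per battery item,
aligned to battery order by label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError


class Domain(str, Enum):
    NEUROCOGNITIVE = "neurocognitive"
    AFFECTIVE = "affective"
    PSYCHOSOCIAL = "psychosocial"


class Orientation(str, Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    HIGHER_IS_WORSE = "higher_is_worse"


@dataclass(frozen=True)
class Item:
    """One instrument item: a node of the network.

    ``score_min``/``score_max`` are the published bounds of the instrument
    and are used both for input validation and to clamp simulated scores.
    """

    label: str
    full_name: str
    domain: Domain
    score_min: float
    score_max: float
    orientation: Orientation

    def __post_init__(self) -> None:
        if not self.score_min < self.score_max:
            raise ValidationError(
                f"item {self.label!r}: score_min must be < score_max "
                f"(got {self.score_min}, {self.score_max})"
            )


@dataclass(frozen=True)
class Battery:
    """Ordered collection of items with unique labels."""

    items: tuple[Item, ...]
    name: str = "battery"

    def __post_init__(self) -> None:
        labels = [it.label for it in self.items]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate item labels: {dupes}")

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    @property
    def domains(self) -> list[Domain]:
        return [it.domain for it in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, label: str) -> Item:
        for it in self.items:
            if it.label == label:
                return it
        raise KeyError(label)

    def index(self, label: str) -> int:
        for i, it in enumerate(self.items):
            if it.label == label:
                return i
        raise KeyError(label)

    def domain_labels(self, domain: Domain | str) -> list[str]:
        domain = Domain(domain)
        return [it.label for it in self.items if it.domain is domain]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "items": [
                {
                    "label": it.label,
                    "full_name": it.full_name,
                    "domain": it.domain.value,
                    "score_min": it.score_min,
                    "score_max": it.score_max,
                    "orientation": it.orientation.value,
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Battery":
        items = tuple(
            Item(
                label=x["label"],
                full_name=x["full_name"],
                domain=Domain(x["domain"]),
                score_min=float(x["score_min"]),
                score_max=float(x["score_max"]),
                orientation=Orientation(x["orientation"]),
            )
            for x in d["items"]
        )
        return cls(items=items, name=d.get("name", "battery"))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Battery":
        p = Path(source)
        if p.exists():
            text = p.read_text(encoding="utf-8")
        else:
            text = str(source)
        return cls.from_dict(json.loads(text))


def _nc(label: str, full_name: str, lo: float, hi: float) -> Item:
    return Item(label, full_name, Domain.NEUROCOGNITIVE, lo, hi,
                Orientation.HIGHER_IS_BETTER)


def _fast(label: str, full_name: str, hi: float) -> Item:
    return Item(label, full_name, Domain.PSYCHOSOCIAL, 0, hi,
                Orientation.HIGHER_IS_WORSE)


def default_battery() -> Battery:
    """The 17-item neurocognitive/affective/psychosocial battery.

    Nine neurocognitive tests (global screening plus specific functions),
    two depression-severity scales, and the six FAST psychosocial domains.
    Score ranges are the instruments' published bounds.
    """
    items = (
        _nc("MCA", "Montreal Cognitive Assessment", 0, 30),
        _nc("MMS", "Mini Mental State Examination", 0, 30),
        _nc("FAB", "Frontal Assessment Battery", 0, 18),
        _nc("FAS", "Phonemic verbal fluency", 0, 60),
        _nc("Vcb", "Vocabulary (WAIS-IV)", 0, 57),
        _nc("REY", "Rey 15 Words immediate recall", 0, 75),
        _nc("RDC", "Rey 15 Words deferred recall", 0, 15),
        _nc("SPAN_A", "Digit span forward", 0, 9),
        _nc("SPAN_I", "Digit span backward", 0, 9),
        Item("BDI", "Beck Depression Inventory II", Domain.AFFECTIVE,
             0, 63, Orientation.HIGHER_IS_WORSE),
        Item("HDR", "Hamilton Depression Rating Scale", Domain.AFFECTIVE,
             0, 52, Orientation.HIGHER_IS_WORSE),
        _fast("Cgn", "FAST cognitive functioning", 15),
        _fast("Occ", "FAST occupational functioning", 15),
        _fast("Atn", "FAST autonomy", 12),
        _fast("Lsr", "FAST leisure time", 6),
        _fast("Int", "FAST interpersonal relationships", 18),
        _fast("Fnn", "FAST financial issues", 6),
    )
    return Battery(items=items, name="default-17")


@dataclass
class ScoreTable:
    """Subjects × items numeric matrix bound to a battery.

    ``values`` is float64 with NaN for missing entries; columns follow
    battery order.
    """

    battery: Battery
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.battery):
            raise ValidationError(
                f"values must be (n_subjects, {len(self.battery)}), "
                f"got {self.values.shape}"
            )
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValidationError("subject_ids length mismatch")
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        for j, item in enumerate(self.battery.items):
            col = self.values[:, j]
            bad = np.where(~np.isnan(col) & ((col < item.score_min) | (col > item.score_max)))[0]
            if bad.size:
                i = int(bad[0])
                raise ValidationError(
                    f"value {col[i]!r} out of range [{item.score_min}, "
                    f"{item.score_max}] for item {item.label!r} "
                    f"(subject {self.subject_ids[i]!r}, row {i})"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.battery.labels)

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.battery.index(label)]


def read_scores(path: str | Path, battery: Battery) -> ScoreTable:
    """Read a delimited score file and align its columns to battery order.

    The file must have a header naming every battery label (any column
    order; extra columns are ignored).  Values outside an item's declared
    range raise :class:`ValidationError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [l for l in battery.labels if l not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {missing}"
        )
    id_col = df.columns[0] if df.columns[0] not in battery.labels else None
    if id_col is not None:
        subject_ids = [str(x) for x in df[id_col]]
    else:
        subject_ids = [f"S{i:04d}" for i in range(len(df))]
    values = df[battery.labels].to_numpy(dtype=float)
    return ScoreTable(battery=battery, subject_ids=subject_ids, values=values)


def write_scores(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as delimited text (subject id in first column)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = table.to_frame()
    df.index.name = "subject"
    df.to_csv(path, sep=sep)
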