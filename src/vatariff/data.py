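"""Data model and delimited-text I/O for verbal autopsy (VA) datasets.

A verbal autopsy is a structured interview with relatives of a deceased
person about the terminal illness.  Each decedent is one :class:`VARecord`
holding binary item endorsements (1 = the informant answered "yes"),
demographics, an optional free-text narrative, and — for gold-standard
training data — the cause of death established from hospital records.

Items are governed by an :class:`ItemDictionary` that classifies each item
by source (closed-ended question vs. narrative-derived text item) and by
whether answering it depends on the family's health care experience (HCE):
diagnoses of chronic illness and interactions with health services are
HCE-dependent, while symptoms and risk behaviors are not.  Analyses are run
"with HCE" (all items) and "without HCE" (symptom and risk-behavior
question items only); :func:`strip_hce` produces the latter condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODULES = ("adult", "child", "neonate")
SEXES = ("male", "female", "unknown")

#: demographic / bookkeeping columns in a dataset file; every other column
#: must be an item declared in the dictionary (unknown ones are ignored).
RESERVED_COLUMNS = ("id", "module", "sex", "age", "site", "gs_cause", "narrative")

_TRUE = {"1", "yes", "y", "true"}
_FALSE = {"0", "no", "n", "false"}


class DataError(ValueError):
    """Raised for malformed datasets, dictionaries, or cause lists."""


@dataclass(frozen=True)
class Item:
    """One questionnaire or text item."""

    item_id: str
    label: str
    source: str  # "question" | "text"
    hce_dependent: bool
    module: str

    def __post_init__(self) -> None:
        if self.source not in ("question", "text"):
            raise DataError(f"item {self.item_id!r}: bad source {self.source!r}")
        if self.module not in MODULES:
            raise DataError(f"item {self.item_id!r}: bad module {self.module!r}")


class ItemDictionary:
    """Item metadata keyed by item id.

    Order of insertion fixes the canonical item order used for matrices.
    """

    def __init__(self, items: Iterable[Item]):
        self._items: dict[str, Item] = {}
        for it in items:
            if it.item_id in self._items:
                raise DataError(f"duplicate item id {it.item_id!r}")
            self._items[it.item_id] = it

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __getitem__(self, item_id: str) -> Item:
        return self._items[item_id]

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self._items.values())

    def item_ids(self, module: str | None = None) -> tuple[str, ...]:
        return tuple(
            i.item_id for i in self if module is None or i.module == module
        )

    def hce_item_ids(self, module: str | None = None) -> tuple[str, ...]:
        return tuple(
            i.item_id
            for i in self
            if i.hce_dependent and (module is None or i.module == module)
        )

    def subset(self, item_ids: Iterable[str]) -> "ItemDictionary":
        keep = set(item_ids)
        return ItemDictionary(i for i in self if i.item_id in keep)

    def extended(self, items: Iterable[Item]) -> "ItemDictionary":
        """New dictionary with extra items appended (used for text items)."""
        return ItemDictionary(list(self) + list(items))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ItemDictionary":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"item_id", "label", "source", "hce_dependent", "module"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"item dictionary {path}: missing columns {sorted(missing)}")
        items = [
            Item(
                item_id=r.item_id,
                label=r.label,
                source=r.source,
                hce_dependent=_parse_bool(r.hce_dependent, path, r.item_id),
                module=r.module,
            )
            for r in df.itertuples()
        ]
        return cls(items)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "item_id": [i.item_id for i in self],
                "label": [i.label for i in self],
                "source": [i.source for i in self],
                "hce_dependent": [int(i.hce_dependent) for i in self],
                "module": [i.module for i in self],
            }
        ).to_csv(path, index=False)


def _parse_bool(value: str, where, key) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise DataError(f"{where}: unparseable boolean {value!r} for {key!r}")


@dataclass(frozen=True)
class CauseList:
    """Ordered module-specific cause-of-death list.

    Its length is the N of the chance-corrected concordance equation.
    """

    module: str
    cause_ids: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)
    residual: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.cause_ids)) != len(self.cause_ids):
            raise DataError("cause ids must be unique")
        if self.module not in MODULES:
            raise DataError(f"bad module {self.module!r}")

    def __len__(self) -> int:
        return len(self.cause_ids)

    def __contains__(self, cause_id: str) -> bool:
        return cause_id in self.cause_ids

    def __iter__(self) -> Iterator[str]:
        return iter(self.cause_ids)

    def index(self, cause_id: str) -> int:
        return self.cause_ids.index(cause_id)

    @classmethod
    def from_csv(cls, path: str | Path, module: str | None = None) -> "CauseList":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"cause_id", "label", "module", "residual"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"cause list {path}: missing columns {sorted(missing)}")
        if module is not None:
            df = df[df["module"] == module]
        modules = df["module"].unique()
        if len(modules) != 1:
            raise DataError(f"cause list {path}: expected one module, got {list(modules)}")
        return cls(
            module=modules[0],
            cause_ids=tuple(df["cause_id"]),
            labels=dict(zip(df["cause_id"], df["label"])),
            residual=frozenset(
                c for c, r in zip(df["cause_id"], df["residual"]) if _parse_bool(r, path, c)
            ),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "cause_id": list(self.cause_ids),
                "label": [self.labels.get(c, c) for c in self.cause_ids],
                "module": self.module,
                "residual": [int(c in self.residual) for c in self.cause_ids],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class VARecord:
    """One decedent.

    ``responses`` maps item id -> {0, 1}; an absent item means 0 (absent
    answers are normalized to 0 at load time, with a logged count).
    """

    id: str
    module: str
    sex: str
    age: float
    site: str
    responses: Mapping[str, int]
    narrative: str | None = None
    gold_standard: str | None = None

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise DataError(f"record {self.id!r}: bad module {self.module!r}")
        if self.sex not in SEXES:
            raise DataError(f"record {self.id!r}: bad sex {self.sex!r}")
        if self.age < 0:
            raise DataError(f"record {self.id!r}: negative age")
        for item, v in self.responses.items():
            if v not in (0, 1):
                raise DataError(f"record {self.id!r}: response {item}={v!r} not in {{0,1}}")


class Dataset:
    """A list of same-module VA records plus governing dictionary and causes."""

    def __init__(
        self,
        records: Sequence[VARecord],
        dictionary: ItemDictionary,
        causes: CauseList,
    ):
        records = list(records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate record ids: {dup}")
        modules = {r.module for r in records}
        if len(modules) > 1:
            raise DataError(f"records span multiple modules: {sorted(modules)}")
        module = modules.pop() if modules else causes.module
        if module != causes.module:
            raise DataError(
                f"records are {module!r} but cause list is {causes.module!r}"
            )
        valid = set(dictionary.item_ids(module))
        for r in records:
            unknown = set(r.responses) - valid
            if unknown:
                raise DataError(
                    f"record {r.id!r}: items not in dictionary for module "
                    f"{module!r}: {sorted(unknown)[:5]}"
                )
            if r.gold_standard is not None and r.gold_standard not in causes:
                raise DataError(
                    f"record {r.id!r}: unknown gold-standard cause {r.gold_standard!r}"
                )
        self.records: list[VARecord] = records
        self.dictionary = dictionary
        self.causes = causes
        self.module = module

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VARecord]:
        return iter(self.records)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return self.dictionary.item_ids(self.module)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def gold_standards(self) -> list[str | None]:
        return [r.gold_standard for r in self.records]

    def response_matrix(self, item_ids: Sequence[str] | None = None) -> np.ndarray:
        """n_records x n_items {0,1} matrix in the given item order."""
        items = list(item_ids if item_ids is not None else self.item_ids)
        X = np.zeros((len(self.records), len(items)), dtype=np.int8)
        col = {it: j for j, it in enumerate(items)}
        for i, r in enumerate(self.records):
            for it, v in r.responses.items():
                j = col.get(it)
                if j is not None and v:
                    X[i, j] = 1
        return X

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.records[i] for i in indices], self.dictionary, self.causes)

    def to_frame(self) -> pd.DataFrame:
        items = self.item_ids
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "module": r.module,
                "sex": r.sex,
                "age": r.age,
                "site": r.site,
                "gs_cause": r.gold_standard or "",
                "narrative": r.narrative or "",
            }
            for it in items:
                row[it] = int(r.responses.get(it, 0))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(RESERVED_COLUMNS) + list(items))


def load_dataset(
    path: str | Path, dictionary: ItemDictionary, causes: CauseList
) -> Dataset:
    """Load a VA dataset from CSV.

    Column dialect: comma-delimited, UTF-8, header required; ``yes``/``no``
    accepted as aliases of 1/0 case-insensitively.  Blank responses are
    normalized to 0 and counted per column in the log.  Unknown columns are
    logged and ignored.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns or "module" not in df.columns:
        raise DataError(f"{path}: required columns 'id' and 'module' missing")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise DataError(f"{path}: duplicate ids {sorted(set(dup))}")
    modules = df["module"].unique()
    if len(modules) != 1:
        raise DataError(f"{path}: expected a single module, got {list(modules)}")
    module = modules[0]
    item_cols = [c for c in df.columns if c in dictionary and dictionary[c].module == module]
    unknown = [c for c in df.columns if c not in RESERVED_COLUMNS and c not in item_cols]
    if unknown:
        logger.info("%s: ignoring %d unknown columns: %s", path, len(unknown), unknown[:10])

    blank_counts: dict[str, int] = {}
    records = []
    for i, row in df.iterrows():
        responses: dict[str, int] = {}
        for c in item_cols:
            raw = str(row[c]).strip().lower()
            if raw == "":
                blank_counts[c] = blank_counts.get(c, 0) + 1
                continue
            if raw in _TRUE:
                responses[c] = 1
            elif raw in _FALSE:
                pass  # explicit 0; absent from the sparse map
            else:
                raise DataError(
                    f"{path}: unparseable response {row[c]!r} in row id="
                    f"{row['id']!r}, column {c!r}"
                )
        gs = str(row.get("gs_cause", "")).strip()
        narrative = str(row.get("narrative", "")).strip()
        records.append(
            VARecord(
                id=str(row["id"]),
                module=module,
                sex=str(row.get("sex", "unknown")).strip().lower() or "unknown",
                age=float(row.get("age", 0) or 0),
                site=str(row.get("site", "")).strip(),
                responses=responses,
                narrative=narrative or None,
                gold_standard=gs or None,
            )
        )
    if blank_counts:
        total = sum(blank_counts.values())
        logger.info(
            "%s: normalized %d blank responses to 0 (per column: %s)",
            path,
            total,
            dict(sorted(blank_counts.items())),
        )
    return Dataset(records, dictionary, causes)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def strip_hce(dataset: Dataset, keep_text: bool = False) -> Dataset:
    """Restrict a dataset to the no-HCE condition.

    Removes HCE-dependent question items; free-text items are removed too
    unless ``keep_text`` (the no-HCE condition uses symptom and
    risk-behavior question items only).  Idempotent.
    """
    def keep(item: Item) -> bool:
        if item.hce_dependent:
            return False
        if item.source == "text" and not keep_text:
            return False
        return True

    new_dict = ItemDictionary(i for i in dataset.dictionary if keep(i))
    kept = set(new_dict.item_ids(dataset.module))
    new_records = [
        replace(r, responses={k: v for k, v in r.responses.items() if k in kept})
        for r in dataset.records
    ]
    return Dataset(new_records, new_dict, dataset.causes)
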