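"""Reading and writing coded corpora.

Two on-disk dialects:

* **JSON** (canonical, lossless): one document per corpus with an explicit
  schema tag ``"culsel-corpus-v1"``; productions as generation-major nested
  lists; the pairing schedule spelled out.
* **CSV** (flat, for inspection/interoperability): one row per production
  with columns ``society_id, concept_id, generation, participant, pair_id,
  drew_second, label``. The variant universe is not stored explicitly, so a
  universe extended beyond the attested labels does not survive a CSV
  round-trip.

Participants and generations are numbered from 1 in files (matching how
such game grids are usually displayed, P1-P8 / G1-G7) and from 0 in memory.
All read paths validate structural invariants before returning.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .datamodel import Corpus, DataStructure, PairingSchedule, ValidationError

__all__ = ["SCHEMA", "CorpusFormatError", "read_corpus", "write_corpus"]

SCHEMA = "culsel-corpus-v1"

_CSV_COLUMNS = [
    "society_id",
    "concept_id",
    "generation",
    "participant",
    "pair_id",
    "drew_second",
    "label",
]


class CorpusFormatError(ValueError):
    """The file could not be parsed in the declared dialect."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "json"


def _structure_to_obj(d: DataStructure) -> dict:
    return {
        "society_id": d.society_id,
        "concept_id": d.concept_id,
        "n_participants": d.n_participants,
        "n_generations": d.n_generations,
        "universe": sorted(d.universe),
        "productions": [list(row) for row in d.productions],
        "schedule": {
            "pairs": [
                [[a + 1, b + 1] for a, b in pairs] for pairs in d.schedule.rounds
            ],
            "second_drawers": [
                [s + 1 for s in seconds] for seconds in d.schedule.second_drawers
            ],
        },
    }


def _structure_from_obj(obj: dict, index: int) -> DataStructure:
    try:
        sched = obj["schedule"]
        schedule = PairingSchedule(
            rounds=tuple(
                tuple((min(a, b) - 1, max(a, b) - 1) for a, b in pairs)
                for pairs in sched["pairs"]
            ),
            second_drawers=tuple(
                tuple(s - 1 for s in seconds) for seconds in sched["second_drawers"]
            ),
        )
        d = DataStructure(
            society_id=obj["society_id"],
            concept_id=obj["concept_id"],
            productions=tuple(tuple(row) for row in obj["productions"]),
            schedule=schedule,
            universe=frozenset(obj.get("universe") or ()),
            n_participants=obj.get("n_participants", 8),
            n_generations=obj.get("n_generations", 7),
        )
    except (KeyError, TypeError) as exc:
        raise CorpusFormatError(f"data structure record {index}: missing/bad field {exc}") from exc
    d.validate()
    return d


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus; the file round-trips through :func:`read_corpus`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    corpus.validate()
    if fmt == "json":
        doc = {
            "schema": SCHEMA,
            "metadata": corpus.metadata,
            "data_structures": [_structure_to_obj(d) for d in corpus],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for d in corpus:
                pair_ids = _pair_id_maps(d.schedule)
                for g, row in enumerate(d.productions):
                    for p, label in enumerate(row):
                        writer.writerow(
                            [
                                d.society_id,
                                d.concept_id,
                                g + 1,
                                p + 1,
                                pair_ids[g][p],
                                int(d.schedule.drew_second(p, g)),
                                label,
                            ]
                        )
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def _pair_id_maps(schedule: PairingSchedule) -> list[dict[int, str]]:
    """Letter pair-ids (A, B, ...) per generation, in pair order."""
    out = []
    for pairs in schedule.rounds:
        mapping: dict[int, str] = {}
        for i, (a, b) in enumerate(pairs):
            letter = chr(ord("A") + i)
            mapping[a] = letter
            mapping[b] = letter
        out.append(mapping)
    return out


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read and validate a corpus from JSON or CSV.

    Raises :class:`CorpusFormatError` on parse problems (naming the record)
    and :class:`culsel.datamodel.ValidationError` when a parsed structure
    breaks an invariant (naming the structure and rule).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        if not isinstance(doc, dict) or doc.get("schema") != SCHEMA:
            raise CorpusFormatError(f"{path}: missing or unknown schema tag (expected {SCHEMA!r})")
        structures = [
            _structure_from_obj(obj, i) for i, obj in enumerate(doc.get("data_structures", []))
        ]
        corpus = Corpus(data_structures=structures, metadata=doc.get("metadata", {}))
    elif fmt == "csv":
        corpus = _read_csv(path)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    corpus.validate()
    return corpus


def _read_csv(path: Path) -> Corpus:
    try:
        frame = pd.read_csv(path, dtype={"label": str, "pair_id": str})
    except Exception as exc:
        raise CorpusFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing CSV columns {sorted(missing)}")

    structures = []
    for (society, concept), group in frame.groupby(["society_id", "concept_id"], sort=True):
        gens = sorted(group["generation"].unique())
        parts = sorted(group["participant"].unique())
        n_g, n_p = len(gens), len(parts)
        if gens != list(range(1, n_g + 1)) or parts != list(range(1, n_p + 1)):
            raise CorpusFormatError(
                f"({society}, {concept}): generations/participants must be 1..G and 1..N"
            )
        if len(group) != n_g * n_p:
            raise ValidationError(
                f"data structure ({society}, {concept}): expected {n_g * n_p} "
                f"productions, found {len(group)}"
            )
        productions = [["" for _ in range(n_p)] for _ in range(n_g)]
        rounds = []
        seconds = []
        for g in range(1, n_g + 1):
            sub = group[group["generation"] == g]
            by_pair: dict[str, list[int]] = {}
            second_set = []
            for _, rec in sub.iterrows():
                p = int(rec["participant"]) - 1
                productions[g - 1][p] = str(rec["label"])
                by_pair.setdefault(str(rec["pair_id"]), []).append(p)
                if int(rec["drew_second"]):
                    second_set.append(p)
            pairs = []
            pair_seconds = []
            for pid in sorted(by_pair):
                members = sorted(by_pair[pid])
                if len(members) != 2:
                    raise CorpusFormatError(
                        f"({society}, {concept}) generation {g}: pair {pid!r} has "
                        f"{len(members)} members"
                    )
                pairs.append((members[0], members[1]))
                in_pair = [p for p in second_set if p in members]
                if len(in_pair) != 1:
                    raise CorpusFormatError(
                        f"({society}, {concept}) generation {g}: pair {pid!r} needs "
                        f"exactly one second drawer"
                    )
                pair_seconds.append(in_pair[0])
            rounds.append(tuple(pairs))
            seconds.append(tuple(pair_seconds))
        d = DataStructure(
            society_id=str(society),
            concept_id=str(concept),
            productions=tuple(tuple(row) for row in productions),
            schedule=PairingSchedule(rounds=tuple(rounds), second_drawers=tuple(seconds)),
            n_participants=n_p,
            n_generations=n_g,
        )
        d.validate()
        structures.append(d)
    return Corpus(data_structures=structures)
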