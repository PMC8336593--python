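"""Design-matrix construction for dose–response quintuplets.

Each measurement is indexed by a quintuplet — drug A, drug B, the
concentration level of each, and a cell line — which positions it inside a
fifth-order response tensor.  The tensor is flattened into a feature matrix
by one-hot encoding the five components (recommender-system style "tensor
index" features).  Auxiliary blocks can be appended: a binary substructure
fingerprint per drug slot and one block per omics type for the cell line.
A monotherapy row leaves the drug-B and concentration-B one-hot spans (and
the drug-B fingerprint span) all zero.

The :class:`FeatureLayout` records the exact column span and vocabulary of
every block so that trained model weights can later be mapped back to named
features, and so that a matrix built at prediction time can be checked
against the layout used in training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import homogenize

__all__ = [
    "MONO",
    "RESPONSE_COLUMNS",
    "FeatureBlock",
    "FeatureLayout",
    "Vocabulary",
    "validate_records",
    "build_vocabulary",
    "encode_tensor_indices",
    "filter_fingerprints",
    "select_omics",
    "assemble",
    "decode_row",
    "read_responses",
    "write_responses",
    "read_feature_table",
]

#: Sentinel drug id marking a monotherapy row (drug B absent).
MONO = "MONO"

RESPONSE_COLUMNS = ["drug_a", "drug_b", "conc_a", "conc_b", "cell_line", "response"]

INDEX_BLOCKS = ["drug_a_onehot", "drug_b_onehot", "conc_a_onehot",
                "conc_b_onehot", "cell_onehot"]


@dataclass(frozen=True)
class FeatureBlock:
    name: str
    start: int
    stop: int           # exclusive
    feature_names: tuple[str, ...]

    @property
    def width(self) -> int:
        return self.stop - self.start

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class FeatureLayout:
    """Ordered, contiguous, non-overlapping blocks covering the raw matrix.

    The homogeneous constant, when present, is the final single-column block
    named ``constant``; all other bookkeeping refers to the raw columns.
    """

    blocks: list[FeatureBlock] = field(default_factory=list)
    homogenized: bool = False

    def add(self, name: str, feature_names: list[str]) -> None:
        if any(b.name == name for b in self.blocks):
            raise ValueError(f"duplicate block name {name!r}")
        start = self.width
        self.blocks.append(
            FeatureBlock(name, start, start + len(feature_names), tuple(feature_names))
        )

    @property
    def width(self) -> int:
        return self.blocks[-1].stop if self.blocks else 0

    def block(self, name: str) -> FeatureBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no feature block named {name!r}; "
                       f"have {[b.name for b in self.blocks]}")

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    @property
    def column_names(self) -> list[str]:
        return [f"{b.name}:{f}" for b in self.blocks for f in b.feature_names]

    def validate(self) -> None:
        pos = 0
        for b in self.blocks:
            if b.start != pos or b.stop < b.start:
                raise ValueError(f"block {b.name!r} spans [{b.start}, {b.stop}) "
                                 f"but expected to start at {pos}")
            pos = b.stop

    def to_json(self) -> str:
        return json.dumps({
            "homogenized": self.homogenized,
            "blocks": [
                {"name": b.name, "start": b.start, "stop": b.stop,
                 "features": list(b.feature_names)}
                for b in self.blocks
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "FeatureLayout":
        obj = json.loads(text)
        layout = cls(homogenized=obj["homogenized"])
        for b in obj["blocks"]:
            layout.blocks.append(
                FeatureBlock(b["name"], b["start"], b["stop"], tuple(b["features"]))
            )
        layout.validate()
        return layout


@dataclass(frozen=True)
class Vocabulary:
    """Deterministic (sorted) id vocabularies for the five index components."""

    drugs: tuple[str, ...]
    conc_levels: tuple[int, ...]
    cells: tuple[str, ...]

    @classmethod
    def from_records(cls, records: pd.DataFrame, n_conc: int | None = None) -> "Vocabulary":
        drugs = set(records["drug_a"].astype(str))
        drugs |= set(records.loc[records["drug_b"].astype(str) != MONO, "drug_b"].astype(str))
        levels = set(int(v) for v in records["conc_a"])
        levels |= set(int(v) for v in records.loc[records["conc_b"] != 0, "conc_b"])
        if n_conc is not None:
            levels |= set(range(1, n_conc + 1))
        return cls(
            drugs=tuple(sorted(drugs)),
            conc_levels=tuple(sorted(levels)),
            cells=tuple(sorted(set(records["cell_line"].astype(str)))),
        )


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the response-table schema and the quintuplet invariants."""
    missing = [c for c in RESPONSE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"response table is missing columns {missing}")
    rec = records.copy()
    rec["drug_a"] = rec["drug_a"].astype(str)
    rec["drug_b"] = rec["drug_b"].astype(str)
    rec["cell_line"] = rec["cell_line"].astype(str)
    rec["conc_a"] = rec["conc_a"].astype(int)
    rec["conc_b"] = rec["conc_b"].astype(int)
    rec["response"] = rec["response"].astype(float)
    if not np.all(np.isfinite(rec["response"])):
        raise ValueError("non-finite response values")
    mono = rec["drug_b"] == MONO
    if (rec.loc[~mono, "drug_a"] == rec.loc[~mono, "drug_b"]).any():
        raise ValueError("combination rows must pair two distinct drugs")
    if (rec.loc[mono, "conc_b"] != 0).any():
        raise ValueError("monotherapy rows must carry conc_b = 0")
    if (rec.loc[~mono, "conc_b"] < 1).any() or (rec["conc_a"] < 1).any():
        raise ValueError("concentration level indices start at 1")
    return rec


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def _onehot(ids, vocab: tuple, block: str) -> np.ndarray:
    index = {v: i for i, v in enumerate(vocab)}
    out = np.zeros((len(ids), len(vocab)))
    for row, val in enumerate(ids):
        if val is None:
            continue
        try:
            out[row, index[val]] = 1.0
        except KeyError:
            raise KeyError(
                f"id {val!r} not in the vocabulary of block {block!r}"
            ) from None
    return out


def encode_tensor_indices(records: pd.DataFrame, vocab: Vocabulary
                          ) -> tuple[np.ndarray, FeatureLayout]:
    """One-hot encode the quintuplet into five blocks.

    A combination row has exactly five ones across the index blocks; a
    monotherapy row has three (its drug-B and conc-B spans stay zero).
    """
    rec = validate_records(records)
    mono = rec["drug_b"] == MONO
    layout = FeatureLayout()
    layout.add("drug_a_onehot", [f"drug={d}" for d in vocab.drugs])
    layout.add("drug_b_onehot", [f"drug={d}" for d in vocab.drugs])
    layout.add("conc_a_onehot", [f"level={c}" for c in vocab.conc_levels])
    layout.add("conc_b_onehot", [f"level={c}" for c in vocab.conc_levels])
    layout.add("cell_onehot", [f"cell={c}" for c in vocab.cells])
    cols = [
        _onehot(rec["drug_a"], vocab.drugs, "drug_a_onehot"),
        _onehot([None if m else d for d, m in zip(rec["drug_b"], mono)],
                vocab.drugs, "drug_b_onehot"),
        _onehot(rec["conc_a"], vocab.conc_levels, "conc_a_onehot"),
        _onehot([None if m else c for c, m in zip(rec["conc_b"], mono)],
                vocab.conc_levels, "conc_b_onehot"),
        _onehot(rec["cell_line"], vocab.cells, "cell_onehot"),
    ]
    return np.hstack(cols), layout


def decode_row(row: np.ndarray, layout: FeatureLayout) -> dict:
    """Invert the one-hot index blocks of a single encoded row."""
    out: dict = {}
    for name, key in [("drug_a_onehot", "drug_a"), ("drug_b_onehot", "drug_b"),
                      ("conc_a_onehot", "conc_a"), ("conc_b_onehot", "conc_b"),
                      ("cell_onehot", "cell_line")]:
        b = layout.block(name)
        hot = np.flatnonzero(row[b.slice])
        if len(hot) == 0:
            out[key] = MONO if key == "drug_b" else 0
        else:
            label = b.feature_names[hot[0]].split("=", 1)[1]
            out[key] = int(label) if key.startswith("conc") else label
    return out


def filter_fingerprints(fp: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop substructure bits present in all drugs or in none.

    Constant bits carry no information and inflate the feature space; the
    surviving columns keep their original order.  Returns the reduced table
    and the kept column labels.
    """
    values = fp.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("fingerprint matrix must be binary (0/1)")
    sums = values.sum(axis=0)
    keep = [c for c, s in zip(fp.columns, sums) if 0 < s < len(fp)]
    return fp[keep], keep


def select_omics(omics: pd.DataFrame, fraction: float) -> tuple[pd.DataFrame, list]:
    """Keep the top-variance fraction of omics features.

    Variance is the unbiased sample variance across cell lines; the number
    kept is ``ceil(fraction * n_features)``, ties resolved in favor of the
    earlier column, and the kept columns retain their original order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if len(omics) < 2:
        raise ValueError("need at least two cell lines to compute variance")
    var = omics.to_numpy().var(axis=0, ddof=1)
    k = math.ceil(fraction * omics.shape[1])
    order = np.argsort(-var, kind="stable")[:k]
    if var[order].max(initial=0.0) == 0.0:
        raise ValueError("no omics feature with positive variance survives selection")
    keep_idx = np.sort(order)
    keep = [omics.columns[i] for i in keep_idx]
    return omics[keep], keep


def _lookup_rows(table: pd.DataFrame, ids, what: str) -> np.ndarray:
    missing = sorted(set(str(i) for i in ids if i is not None) - set(table.index.astype(str)))
    if missing:
        raise KeyError(f"{what} table has no rows for ids {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    out = np.zeros((len(ids), table.shape[1]))
    idx = {str(k): j for j, k in enumerate(table.index)}
    values = table.to_numpy(dtype=float)
    for row, i in enumerate(ids):
        if i is not None:
            out[row] = values[idx[str(i)]]
    return out


def assemble(records: pd.DataFrame,
             vocab: Vocabulary | None = None,
             fingerprints: pd.DataFrame | None = None,
             omics: dict[str, pd.DataFrame] | None = None,
             zscore_auxiliary: bool = False,
             ) -> tuple[np.ndarray, FeatureLayout]:
    """Build the full design matrix: index blocks, optional fingerprint
    blocks (one per drug slot), optional per-type omics blocks, and the
    trailing homogeneous constant.

    Drug-level auxiliary features are inserted once per drug slot (``fp_a``
    from drug A, ``fp_b`` from drug B, zero for monotherapy rows);
    cell-level blocks once.  ``zscore_auxiliary`` standardizes the
    continuous omics columns, whose variances can span orders of magnitude;
    binary fingerprints are always used as provided.
    """
    rec = validate_records(records)
    if vocab is None:
        vocab = Vocabulary.from_records(rec)
    X, layout = encode_tensor_indices(rec, vocab)
    parts = [X]
    mono = (rec["drug_b"] == MONO).to_numpy()

    def _maybe_z(arr: np.ndarray) -> np.ndarray:
        if not zscore_auxiliary:
            return arr
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0)
        sd[sd == 0] = 1.0
        return (arr - mu) / sd

    if fingerprints is not None:
        fp_a = _lookup_rows(fingerprints, rec["drug_a"], "fingerprint")
        ids_b = [None if m else d for d, m in zip(rec["drug_b"], mono)]
        fp_b = _lookup_rows(fingerprints, ids_b, "fingerprint")
        names = [str(c) for c in fingerprints.columns]
        layout.add("fp_a", names)
        layout.add("fp_b", names)
        parts += [fp_a, fp_b]
    for omics_name, table in (omics or {}).items():
        block = _lookup_rows(table, rec["cell_line"], f"omics[{omics_name}]")
        layout.add(f"omics_{omics_name}", [str(c) for c in table.columns])
        parts.append(_maybe_z(block))

    X_raw = np.hstack(parts)
    X_full = homogenize(X_raw)
    layout.add("constant", ["1"])
    layout.homogenized = True
    layout.validate()
    return X_full, layout


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def read_responses(path) -> pd.DataFrame:
    """Read the long-format response table (TSV/CSV sniffed by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    rec = pd.read_csv(path, sep=sep, dtype={"drug_a": str, "drug_b": str,
                                            "cell_line": str})
    return validate_records(rec)


def write_responses(records: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    records[RESPONSE_COLUMNS].to_csv(path, sep=sep, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a drug-fingerprint or omics table; first column is the id index."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.index = table.index.astype(str)
    return table
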