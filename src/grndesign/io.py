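"""File formats: network JSON, trajectory TSV, CPM TSV, uncertainty YAML, policy JSON.

All formats are plain text and round-trip stable.  Validation errors name the
offending file and, for line-oriented formats, the line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .control import Policy
from .cpm_uncertainty import CPMSet, UncertainParam, UncertaintyClass
from .networks import BooleanNetwork, ConfigurationError

__all__ = [
    "save_network",
    "load_network",
    "save_trajectory",
    "load_trajectory",
    "save_cpms",
    "load_cpms",
    "save_uncertainty",
    "load_uncertainty",
    "save_policy",
    "load_policy",
    "parse_state_set",
]


def save_network(path: str | Path, net: BooleanNetwork) -> None:
    if net.truth_tables is not None:
        rule = {"type": "truth_table", "tables": [tt.tolist() for tt in net.truth_tables]}
    else:
        rule = {"type": "majority", "matrix": net.majority_matrix.tolist()}
    doc = {
        "n": net.n,
        "gene_names": list(net.gene_names),
        "regulators": [list(r) for r in net.regulators],
        "rule": rule,
        "p": net.p,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_network(path: str | Path) -> BooleanNetwork:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        rule = doc["rule"]
        names = doc.get("gene_names") or [f"X{i+1}" for i in range(doc["n"])]
        if rule["type"] == "truth_table":
            net = BooleanNetwork.from_truth_tables(
                doc["regulators"], rule["tables"], p=doc["p"], gene_names=names
            )
        elif rule["type"] == "majority":
            net = BooleanNetwork.from_majority(
                np.asarray(rule["matrix"]), p=doc["p"], gene_names=names
            )
        else:
            raise ConfigurationError(f"{path}: unknown rule type {rule['type']!r}")
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing field {exc}") from exc
    if net.n != doc["n"]:
        raise ConfigurationError(f"{path}: declared n={doc['n']} but found {net.n} genes")
    return net


def save_trajectory(path: str | Path, states) -> None:
    Path(path).write_text("\n".join(str(int(s)) for s in states) + "\n")


def load_trajectory(path: str | Path, n: int | None = None) -> np.ndarray:
    path = Path(path)
    states = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            s = int(line)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a decimal state: {line!r}") from exc
        if s < 0 or (n is not None and s >= 2 ** n):
            raise ValueError(f"{path}:{lineno}: state {s} out of range for n={n}")
        states.append(s)
    return np.asarray(states, dtype=np.int64)


def save_cpms(directory: str | Path, cpms: CPMSet) -> None:
    """One TSV per gene (rows: Pr[X_i=0], Pr[X_i=1]) plus a regulator manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, tab in enumerate(cpms.tables):
        lines = ["\t".join(f"{v:.17g}" for v in row) for row in tab]
        (directory / f"cpm_gene{i}.tsv").write_text("\n".join(lines) + "\n")
    manifest = {"n": cpms.n, "regulators": [list(r) for r in cpms.regulators]}
    (directory / "regulators.json").write_text(json.dumps(manifest, indent=1) + "\n")


def load_cpms(directory: str | Path) -> CPMSet:
    directory = Path(directory)
    manifest = json.loads((directory / "regulators.json").read_text())
    tables = []
    for i in range(manifest["n"]):
        f = directory / f"cpm_gene{i}.tsv"
        rows = []
        for lineno, line in enumerate(f.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(f"{f}:{lineno}: expected two columns")
            rows.append([float(parts[0]), float(parts[1])])
        tables.append(np.asarray(rows))
    return CPMSet(
        tuple(tables), tuple(tuple(int(g) for g in r) for r in manifest["regulators"])
    )


def save_uncertainty(path: str | Path, unc: UncertaintyClass) -> None:
    docs = []
    for p in unc.params:
        d = {"gene": p.gene, "row": p.row, "alpha": float(p.alpha), "beta": float(p.beta)}
        if p.revealed:
            d["value"] = float(p.value)
        docs.append(d)
    Path(path).write_text(yaml.safe_dump(docs, sort_keys=False))


def load_uncertainty(path: str | Path) -> UncertaintyClass:
    path = Path(path)
    docs = yaml.safe_load(path.read_text())
    if not isinstance(docs, list):
        raise ConfigurationError(f"{path}: expected a YAML list of parameters")
    params = []
    for k, d in enumerate(docs):
        try:
            params.append(
                UncertainParam(
                    gene=int(d["gene"]),
                    row=int(d["row"]),
                    alpha=float(d["alpha"]),
                    beta=float(d["beta"]),
                    value=float(d["value"]) if "value" in d else None,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigurationError(f"{path}: entry {k}: {exc}") from exc
    return UncertaintyClass(tuple(params))


def save_policy(path: str | Path, policy: Policy) -> None:
    doc = {"actions": policy.actions.tolist()}
    if policy.J is not None:
        doc["J"] = [float(v) for v in policy.J]
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_policy(path: str | Path) -> Policy:
    doc = json.loads(Path(path).read_text())
    J = np.asarray(doc["J"], dtype=np.float64) if "J" in doc else None
    return Policy(actions=np.asarray(doc["actions"]), J=J)


def parse_state_set(spec: str) -> np.ndarray:
    """Parse a state-set spec like ``"0-15"`` or ``"3,7,12-14"`` into indices."""
    out: list[int] = []
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, hi = chunk.split("-", 1)
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(chunk))
    if not out:
        raise ValueError(f"empty state set spec: {spec!r}")
    return np.unique(np.asarray(out, dtype=np.int64))
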