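"""File formats: network JSON/CSV, timeseries CSV, XYZ/extended-XYZ, events.

The network schema (version 1) is a JSON document::

    {"schema": 1,
     "species": [{"label": ..., "name": ..., "composition": {...},
                  "charge": ..., "rel_G": ..., "tags": [...]}, ...],
     "steps":   [{"id": ..., "reactants": {...}, "products": {...},
                  "Ga_fwd": ..., "dG": ..., "step_class": ...,
                  "Ga_provenance": "text"|"supplementary",
                  "dG_provenance": ...}, ...],
     "meta": {...}}

A flat two-file CSV dialect (``<stem>.species.csv`` / ``<stem>.steps.csv``)
with the same fields is also supported.  Free energies are serialized to
0.1 kcal/mol — the precision of the source data — but held as full floats
in memory.
"""

from __future__ import annotations

import csv
import gzip
import io as _io
import json
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np

from .netmodel import ElementaryStep, ReactionNetwork, Species, validate_network

__all__ = [
    "load_network",
    "save_network",
    "save_timeseries",
    "load_timeseries",
    "read_xyz",
    "write_xyz",
    "write_events",
    "read_events",
    "network_to_graphml",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# reaction networks


def _species_to_record(sp: Species) -> dict:
    rec = {
        "label": sp.label,
        "name": sp.name,
        "composition": dict(sp.composition),
        "charge": sp.charge,
    }
    if sp.rel_G is not None:
        rec["rel_G"] = round(sp.rel_G, 1)
    if sp.tags:
        rec["tags"] = sorted(sp.tags)
    return rec


def _step_to_record(st: ElementaryStep) -> dict:
    prov = st.provenance
    if isinstance(prov, str):
        prov = {"Ga_fwd": prov, "dG": prov}
    return {
        "id": st.id,
        "reactants": dict(st.reactants),
        "products": dict(st.products),
        "Ga_fwd": round(st.Ga_fwd, 1),
        "dG": round(st.dG, 1),
        "step_class": st.step_class,
        "Ga_provenance": prov.get("Ga_fwd", "text"),
        "dG_provenance": prov.get("dG", "text"),
    }


def _species_from_record(rec: dict) -> Species:
    try:
        return Species(
            label=str(rec["label"]),
            name=rec.get("name", ""),
            composition={k: int(v) for k, v in rec.get("composition", {}).items()},
            charge=int(rec.get("charge", 0)),
            rel_G=rec.get("rel_G"),
            tags=frozenset(rec.get("tags", ())),
        )
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"bad species record {rec.get('label', rec)!r}: {exc}")


def _step_from_record(rec: dict) -> ElementaryStep:
    try:
        return ElementaryStep(
            id=str(rec["id"]),
            reactants={k: int(v) for k, v in rec["reactants"].items()},
            products={k: int(v) for k, v in rec["products"].items()},
            Ga_fwd=float(rec["Ga_fwd"]),
            dG=float(rec["dG"]),
            step_class=rec.get("step_class", "other"),
            provenance={
                "Ga_fwd": rec.get("Ga_provenance", "text"),
                "dG": rec.get("dG_provenance", "text"),
            },
        )
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"bad step record {rec.get('id', rec)!r}: {exc}")


def save_network(network: ReactionNetwork, path) -> None:
    """Write a network as schema-1 JSON, or as the CSV pair for ``.csv``."""
    path = Path(path)
    if path.suffix == ".csv":
        _save_network_csv(network, path)
        return
    doc = {
        "schema": SCHEMA_VERSION,
        "species": [_species_to_record(s) for s in network.species],
        "steps": [_step_to_record(s) for s in network.steps],
        "meta": network.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_network(path, validate: bool = True) -> ReactionNetwork:
    """Read a network from schema-1 JSON or the two-file CSV dialect."""
    path = Path(path)
    if path.suffix == ".csv":
        net = _load_network_csv(path)  # checks the pair files itself
    elif not path.exists():
        raise FileNotFoundError(path)
    else:
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema") != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema {doc.get('schema')!r}")
        net = ReactionNetwork(
            species=[_species_from_record(r) for r in doc.get("species", [])],
            steps=[_step_from_record(r) for r in doc.get("steps", [])],
            meta=doc.get("meta", {}),
        )
    if validate:
        report = validate_network(net)
        if report:
            raise SchemaError("; ".join(report))
    return net


def _csv_pair(path: Path) -> tuple[Path, Path]:
    stem = path.name
    for suffix in (".species.csv", ".steps.csv", ".csv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return (
        path.with_name(stem + ".species.csv"),
        path.with_name(stem + ".steps.csv"),
    )


def _save_network_csv(network: ReactionNetwork, path: Path) -> None:
    sp_path, st_path = _csv_pair(path)
    with open(sp_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "name", "composition", "charge", "rel_G", "tags"])
        for sp in network.species:
            w.writerow(
                [
                    sp.label,
                    sp.name,
                    json.dumps(dict(sp.composition)),
                    sp.charge,
                    "" if sp.rel_G is None else round(sp.rel_G, 1),
                    " ".join(sorted(sp.tags)),
                ]
            )
    with open(st_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "id",
                "reactants",
                "products",
                "Ga_fwd",
                "dG",
                "step_class",
                "Ga_provenance",
                "dG_provenance",
            ]
        )
        for st in network.steps:
            rec = _step_to_record(st)
            w.writerow(
                [
                    rec["id"],
                    json.dumps(rec["reactants"]),
                    json.dumps(rec["products"]),
                    rec["Ga_fwd"],
                    rec["dG"],
                    rec["step_class"],
                    rec["Ga_provenance"],
                    rec["dG_provenance"],
                ]
            )


def _load_network_csv(path: Path) -> ReactionNetwork:
    sp_path, st_path = _csv_pair(path)
    for p in (sp_path, st_path):
        if not p.exists():
            raise FileNotFoundError(p)
    species = []
    with open(sp_path, newline="") as fh:
        for row in csv.DictReader(fh):
            species.append(
                _species_from_record(
                    {
                        "label": row["label"],
                        "name": row["name"],
                        "composition": json.loads(row["composition"] or "{}"),
                        "charge": int(row["charge"] or 0),
                        "rel_G": float(row["rel_G"]) if row["rel_G"] else None,
                        "tags": row["tags"].split() if row["tags"] else (),
                    }
                )
            )
    steps = []
    with open(st_path, newline="") as fh:
        for row in csv.DictReader(fh):
            steps.append(
                _step_from_record(
                    {
                        "id": row["id"],
                        "reactants": json.loads(row["reactants"]),
                        "products": json.loads(row["products"]),
                        "Ga_fwd": row["Ga_fwd"],
                        "dG": row["dG"],
                        "step_class": row["step_class"],
                        "Ga_provenance": row["Ga_provenance"],
                        "dG_provenance": row["dG_provenance"],
                    }
                )
            )
    return ReactionNetwork(species, steps, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# timeseries


def save_timeseries(series, path) -> None:
    """CSV with time_s, one column per species (M), one per step net rate."""
    import pandas as pd

    cols = {"time_s": series.times}
    for i, lab in enumerate(series.species):
        cols[f"conc:{lab}"] = series.conc[:, i]
    for j, sid in enumerate(series.step_ids):
        cols[f"net_rate:{sid}"] = series.net_rate[:, j]
    for lab, cum in series.fixed_exchange.items():
        cols[f"fixed_exchange:{lab}"] = cum
    df = pd.DataFrame(cols)
    with _open(path, "wt") as fh:
        df.to_csv(fh, index=False)


def load_timeseries(path):
    """Inverse of :func:`save_timeseries`."""
    import pandas as pd

    from .kinetics import TimeSeries

    with _open(path, "rt") as fh:
        df = pd.read_csv(fh)
    species = [c[5:] for c in df.columns if c.startswith("conc:")]
    step_ids = [c[9:] for c in df.columns if c.startswith("net_rate:")]
    fixed = [c[15:] for c in df.columns if c.startswith("fixed_exchange:")]
    return TimeSeries(
        times=df["time_s"].to_numpy(),
        species=species,
        conc=df[[f"conc:{s}" for s in species]].to_numpy(),
        step_ids=step_ids,
        net_rate=df[[f"net_rate:{s}" for s in step_ids]].to_numpy(),
        fixed_exchange={
            lab: df[f"fixed_exchange:{lab}"].to_numpy() for lab in fixed
        },
    )


# ---------------------------------------------------------------------------
# XYZ / extended-XYZ trajectories


def _scalar_repr(v) -> str:
    """Repr for extended-XYZ comment values (full float precision)."""
    if isinstance(v, str):
        return f'"{v}"'
    try:
        return repr(float(v))
    except (TypeError, ValueError):
        return f'"{v}"'


def write_xyz(path_or_fh, frames, comments=None, mode="w") -> None:
    """Write configuration frames as (extended-)XYZ.

    ``frames`` is an iterable of objects with ``symbols`` and ``positions``;
    ``comments`` an optional parallel iterable of comment strings (plain) or
    dicts (serialized as ``key=value`` pairs, extended-XYZ style).
    Positions are written with ``repr``-level precision so a read-back is
    bit-exact.
    """
    own = isinstance(path_or_fh, (str, Path))
    fh: IO = open(path_or_fh, mode) if own else path_or_fh
    try:
        frames = list(frames) if not isinstance(frames, (list, tuple)) else frames
        if comments is None:
            comments = [""] * len(frames)
        for frame, comment in zip(frames, comments):
            if isinstance(comment, dict):
                comment = " ".join(
                    f"{k}={_scalar_repr(v)}" for k, v in comment.items()
                )
            fh.write(f"{len(frame.symbols)}\n{comment}\n")
            for s, (x, y, z) in zip(frame.symbols, frame.positions):
                fh.write(
                    f"{s} {float(x)!r} {float(y)!r} {float(z)!r}\n"
                )
    finally:
        if own:
            fh.close()


def read_xyz(path) -> Iterator[tuple[list[str], np.ndarray, str]]:
    """Yield (symbols, positions, comment) per frame of an XYZ file."""
    with _open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                return
            n = int(line)
            comment = fh.readline().rstrip("\n")
            symbols, pos = [], np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                symbols.append(parts[0])
                pos[i] = [float(p) for p in parts[1:4]]
            yield symbols, pos, comment


# ---------------------------------------------------------------------------
# reaction events (JSON Lines)


def write_events(events: Iterable, path) -> None:
    with _open(path, "wt") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_record()) + "\n")


def read_events(path) -> list[dict]:
    with _open(path, "rt") as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------


def network_to_graphml(network: ReactionNetwork, path) -> None:
    """Export the species/step bipartite topology for visualization."""
    import networkx as nx

    g = nx.DiGraph()
    for sp in network.species:
        g.add_node(sp.label, kind="species", name=sp.name, charge=sp.charge)
    for st in network.steps:
        g.add_node(st.id, kind="step", step_class=st.step_class)
        for lab, nu in st.reactants.items():
            g.add_edge(lab, st.id, coeff=nu)
        for lab, nu in st.products.items():
            g.add_edge(st.id, lab, coeff=nu)
    nx.write_graphml(g, path)
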