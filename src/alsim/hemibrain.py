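"""Optional converter for hemibrain-style neuprint CSV exports.

Entirely file-based (no network access): takes a neuron table and a
connection table as exported from a neuprint query and rewrites them in
the roster/edge schemas consumed by :mod:`alsim.circuit_model`.

Expected input columns
----------------------
neurons:      ``bodyId``, ``type`` (containing one of ORN/uPN/mPN/LN, e.g.
              "ORN_DA1", "DA1_lPN", "mPN1", "LN2R_a"), and optionally
              ``glomerulus`` — if absent, the glomerulus is parsed from the
              type string for ORNs/uPNs.
connections:  ``bodyId_pre``, ``bodyId_post``, ``weight`` (synapse count).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["convert_neuprint_export"]

_CLASS_PATTERNS = (
    ("ORN", re.compile(r"\bORN[_ ]?([A-Za-z0-9]+)?")),
    ("mPN", re.compile(r"\bmPN|\bM_")),
    ("uPN", re.compile(r"([A-Za-z0-9]+)[_ ]?[al]?PN|\buPN")),
    ("LN", re.compile(r"\bLN")),
)


def _classify(type_str: str) -> tuple[str | None, str | None]:
    s = str(type_str)
    if re.search(r"\bLN", s):
        return "LN", None
    m = re.match(r"ORN[_ ]([A-Za-z0-9+]+)", s)
    if m:
        return "ORN", m.group(1)
    if re.search(r"\bmPN|^M[_ ]", s):
        return "mPN", None
    m = re.match(r"([A-Za-z0-9+]+)[_ ](?:ad|l|v|il|vc)?PN", s)
    if m:
        return "uPN", m.group(1)
    return None, None


def convert_neuprint_export(neurons_csv, connections_csv, out_dir) -> dict[str, Path]:
    """Rewrite a neuprint export in the loader's roster/edge schemas.

    Neurons whose type cannot be mapped to a cell class are dropped with
    their connections.  Returns the paths of the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    neurons = pd.read_csv(neurons_csv)
    conns = pd.read_csv(connections_csv)

    rows = []
    for _, rec in neurons.iterrows():
        cls, glom = _classify(rec["type"])
        if cls is None:
            continue
        if "glomerulus" in neurons.columns and pd.notna(rec.get("glomerulus")):
            glom = rec["glomerulus"]
        rows.append(
            {
                "id": str(rec["bodyId"]),
                "cell_class": cls,
                "glomerulus": glom if cls in ("ORN", "uPN") else "",
                "polarity": 1 if cls == "ORN" else "",
            }
        )
    roster = pd.DataFrame(rows)
    if roster.empty:
        raise ValueError("no neuron types could be mapped to AL cell classes")
    known = set(roster["id"])

    edges = pd.DataFrame(
        {
            "pre_id": conns["bodyId_pre"].astype(str),
            "post_id": conns["bodyId_post"].astype(str),
            "synapse_count": conns["weight"].astype(int),
        }
    )
    edges = edges[edges["pre_id"].isin(known) & edges["post_id"].isin(known)]

    paths = {"roster": out / "roster.tsv", "edges": out / "edges.tsv"}
    roster.to_csv(paths["roster"], sep="\t", index=False)
    edges.to_csv(paths["edges"], sep="\t", index=False)
    return paths
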