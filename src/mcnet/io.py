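"""Reading distance matrices and writing SplitsTree-readable split systems.

Two input formats are supported: the PHYLIP square distance format (taxon
count line followed by labelled rows, relaxed whitespace or strict 10-column
labels, rows may wrap) and NEXUS files with TAXA + DISTANCES blocks
(``triangle=both`` or ``lower``).  Output split systems go into a NEXUS
SPLITS block — the dialect SplitsTree4 reads — with a CYCLE statement giving
the circular ordering and one weighted matrix row per split.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .distmat import DistanceMatrix, ParseError
from .ordering import CircularOrdering
from .splits import Split, WeightedSplitSystem, build_design_matrix, distance_vector

__all__ = [
    "read_distance_matrix",
    "write_distance_matrix",
    "write_splits_nexus",
    "read_splits_nexus",
]


# ---------------------------------------------------------------------------
# distance-matrix input

def read_distance_matrix(path, format: str = "auto") -> DistanceMatrix:
    """Read a distance matrix from PHYLIP or NEXUS.

    ``format='auto'`` sniffs the ``#NEXUS`` header versus a leading integer
    taxon count.  Asymmetries up to 1e-6 are averaged away; larger ones, and
    malformed rows, raise with the offending location named.
    """
    path = Path(path)
    text = path.read_text()
    if format == "auto":
        head = text.lstrip()[:6].upper()
        format = "nexus" if head.startswith("#NEXUS") else "phylip"
    if format == "phylip":
        return _read_phylip(text)
    if format == "nexus":
        return _read_nexus_distances(text)
    raise ValueError(f"unknown format {format!r}")


def _read_phylip(text: str) -> DistanceMatrix:
    lines = [ln for ln in text.splitlines()]
    body = [ln for ln in lines if ln.strip()]
    if not body:
        raise ParseError("empty file")
    try:
        n = int(body[0].split()[0])
    except ValueError:
        raise ParseError(f"first line must be the taxon count, got {body[0]!r}") from None
    labels: list[str] = []
    rows: list[list[float]] = []
    for ln in body[1:]:
        if rows and len(rows[-1]) < n:
            # continuation of a wrapped row: every token must be numeric
            tokens = ln.split()
            try:
                rows[-1].extend(float(t) for t in tokens)
            except ValueError:
                raise ParseError(
                    f"row {len(rows)}: expected {n} values, got {len(rows[-1])}"
                ) from None
            if len(rows[-1]) > n:
                raise ParseError(
                    f"row {len(rows)}: expected {n} values, got {len(rows[-1])}"
                )
            continue
        if len(rows) == n:
            raise ParseError(f"more than {n} rows of data")
        tokens = ln.split()
        relaxed: tuple[str, list[float]] | None = None
        try:
            relaxed = (tokens[0], [float(t) for t in tokens[1:]])
        except ValueError:
            relaxed = None
        if relaxed is not None and len(relaxed[1]) == n:
            label, values = relaxed
        else:
            # strict PHYLIP: label occupies the first 10 columns
            strict_label = ln[:10].strip()
            try:
                strict_values = [float(t) for t in ln[10:].split()]
            except ValueError:
                strict_values = None
            if strict_values is not None and strict_label and len(strict_values) == n:
                label, values = strict_label, strict_values
            elif relaxed is not None:  # short row: may wrap onto the next line
                label, values = relaxed
            elif strict_values is not None and strict_label:
                label, values = strict_label, strict_values
            else:
                raise ParseError(f"row {len(rows) + 1}: unparseable values")
        if len(values) > n:
            raise ParseError(
                f"row {len(rows) + 1}: expected {n} values, got {len(values)}"
            )
        labels.append(label)
        rows.append(values)
    if len(rows) != n:
        raise ParseError(f"expected {n} rows, got {len(rows)}")
    for i, row in enumerate(rows):
        if len(row) != n:
            raise ParseError(f"row {i + 1}: expected {n} values, got {len(row)}")
    return DistanceMatrix(tuple(labels), np.array(rows))


# -- NEXUS ------------------------------------------------------------------

def _strip_nexus_comments(text: str) -> str:
    return re.sub(r"\[[^\]]*\]", " ", text)


def _nexus_blocks(text: str) -> dict[str, list[str]]:
    """Commands of each block, keyed by lower-case block name."""
    text = _strip_nexus_comments(text)
    blocks: dict[str, list[str]] = {}
    for m in re.finditer(r"begin\s+(\w+)\s*;(.*?)\bend\s*;", text,
                         re.IGNORECASE | re.DOTALL):
        name = m.group(1).lower()
        commands = [c.strip() for c in m.group(2).split(";") if c.strip()]
        blocks[name] = commands
    return blocks


def _unquote(token: str) -> str:
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def _parse_taxlabels(commands: list[str]) -> list[str]:
    for cmd in commands:
        if cmd.lower().startswith("taxlabels"):
            tokens = re.findall(r"'[^']*'|\"[^\"]*\"|\S+", cmd[len("taxlabels"):])
            return [_unquote(t) for t in tokens]
    raise ParseError("TAXA block without TAXLABELS")


def _read_nexus_distances(text: str) -> DistanceMatrix:
    blocks = _nexus_blocks(text)
    taxa_block = blocks.get("taxa")
    dist_block = blocks.get("distances")
    if dist_block is None:
        raise ParseError("no DISTANCES block found")
    labels = _parse_taxlabels(taxa_block) if taxa_block else None

    triangle = "lower"
    diagonal = True
    matrix_cmd = None
    for cmd in dist_block:
        low = cmd.lower()
        if low.startswith("format"):
            m = re.search(r"triangle\s*=\s*(\w+)", low)
            if m:
                triangle = m.group(1)
            if re.search(r"\bno\s*diagonal\b|\bnodiagonal\b", low):
                diagonal = False
        elif low.startswith("matrix"):
            matrix_cmd = cmd[len("matrix"):]
        elif low.startswith("dimensions") and labels is None:
            pass  # labels must come from matrix rows
    if matrix_cmd is None:
        raise ParseError("DISTANCES block without MATRIX")

    row_labels: list[str] = []
    rows: list[list[float]] = []
    for ln in matrix_cmd.splitlines():
        if not ln.strip():
            continue
        tokens = [_unquote(t) for t in re.findall(r"'[^']*'|\"[^\"]*\"|\S+", ln)]
        try:
            float(tokens[0])
            label = None
            values = [float(t) for t in tokens]
        except ValueError:
            label = tokens[0]
            try:
                values = [float(t) for t in tokens[1:]]
            except ValueError:
                raise ParseError(f"matrix row {len(rows) + 1}: unparseable values") from None
        row_labels.append(label if label is not None else "")
        rows.append(values)
    if labels is None:
        if any(not lab for lab in row_labels):
            raise ParseError("no taxon labels in TAXA block or matrix rows")
        labels = row_labels
    n = len(labels)
    if len(rows) != n:
        raise ParseError(f"expected {n} matrix rows, got {len(rows)}")

    values = np.zeros((n, n))
    if triangle == "both":
        for i, row in enumerate(rows):
            if len(row) != n:
                raise ParseError(f"matrix row {i + 1}: expected {n} values, got {len(row)}")
            values[i] = row
    elif triangle == "lower":
        for i, row in enumerate(rows):
            expect = i + 1 if diagonal else i
            if len(row) != expect:
                raise ParseError(
                    f"matrix row {i + 1}: expected {expect} values, got {len(row)}"
                )
            cols = row if diagonal else row + [0.0]
            for j, v in enumerate(cols[: i + 1]):
                values[i, j] = v
                values[j, i] = v
    else:
        raise ParseError(f"unsupported triangle={triangle!r}")
    return DistanceMatrix(tuple(labels), values)


# ---------------------------------------------------------------------------
# distance-matrix output

def write_distance_matrix(d: DistanceMatrix, path, format: str = "phylip") -> None:
    """Write a matrix as PHYLIP square or NEXUS TAXA+DISTANCES."""
    path = Path(path)
    if format == "phylip":
        lines = [f"{d.n}"]
        for label, row in zip(d.labels, d.values):
            lines.append(label + " " + " ".join(f"{v:.12g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif format == "nexus":
        out = ["#NEXUS", "", "BEGIN Taxa;", f"DIMENSIONS ntax={d.n};", "TAXLABELS"]
        out += [f"  [{i + 1}] '{lab}'" for i, lab in enumerate(d.labels)]
        out += [";", "END;", "", "BEGIN Distances;", f"DIMENSIONS ntax={d.n};",
                "FORMAT labels=left diagonal triangle=both;", "MATRIX"]
        for label, row in zip(d.labels, d.values):
            out.append(f"  '{label}' " + " ".join(f"{v:.12g}" for v in row))
        out += [";", "END;", ""]
        path.write_text("\n".join(out))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# splits output (SplitsTree4 SPLITS block)

def write_splits_nexus(
    system: WeightedSplitSystem,
    path,
    cycle: CircularOrdering | None = None,
) -> None:
    """Write a weighted split system as a NEXUS file SplitsTree4 can draw.

    Emits a TAXA block and a SPLITS block with a CYCLE statement (1-based
    taxon indices of the circular ordering) and one matrix row per split:
    the weight followed by the 1-based members of the canonical side.  All
    weights must be strictly positive (filter first).
    """
    cycle = cycle or system.cycle
    if cycle.n != system.n:
        raise ValueError("cycle and split system disagree on n")
    weights = np.asarray(system.weights, float)
    if weights.size and weights.min() <= 0:
        raise ValueError("all split weights must be > 0; filter the system first")
    n = system.n
    out = ["#NEXUS", "", "BEGIN Taxa;", f"DIMENSIONS ntax={n};", "TAXLABELS"]
    out += [f"  [{i + 1}] '{lab}'" for i, lab in enumerate(system.labels)]
    out += [";", "END; [Taxa]", "", "BEGIN Splits;",
            f"DIMENSIONS ntax={n} nsplits={len(system.splits)};",
            "FORMAT labels=no weights=yes confidences=no intervals=no;",
            "CYCLE " + " ".join(str(i + 1) for i in cycle.perm) + ";",
            "MATRIX"]
    for s, w in zip(system.splits, weights):
        members = " ".join(str(i + 1) for i in s.side)
        out.append(f"  {w:.12g} {members},")
    out += [";", "END; [Splits]", ""]
    Path(path).write_text("\n".join(out))


def read_splits_nexus(path) -> tuple[tuple[str, ...], CircularOrdering, list[tuple[Split, float]]]:
    """Parse a SPLITS NEXUS file back into (labels, cycle, [(split, weight)]).

    The round-trip partner of :func:`write_splits_nexus`, used to verify
    written files and to re-import split systems.
    """
    text = Path(path).read_text()
    blocks = _nexus_blocks(text)
    if "taxa" not in blocks or "splits" not in blocks:
        raise ParseError("expected TAXA and SPLITS blocks")
    labels = tuple(_parse_taxlabels(blocks["taxa"]))
    n = len(labels)
    cycle = None
    pairs: list[tuple[Split, float]] = []
    for cmd in blocks["splits"]:
        low = cmd.lower()
        if low.startswith("cycle"):
            cycle = CircularOrdering(
                tuple(int(t) - 1 for t in cmd.split()[1:])
            )
        elif low.startswith("matrix"):
            body = cmd[len("matrix"):]
            for entry in body.split(","):
                tokens = entry.split()
                if not tokens:
                    continue
                w = float(tokens[0])
                members = [int(t) - 1 for t in tokens[1:]]
                pairs.append((Split.from_members(members, n), w))
    if cycle is None:
        raise ParseError("SPLITS block without CYCLE")
    return labels, cycle, pairs


def system_from_nexus(path, d: DistanceMatrix | None = None) -> WeightedSplitSystem:
    """Rebuild a :class:`WeightedSplitSystem` from a SPLITS NEXUS file.

    If the source distances ``d`` are given the system's residual can be
    scored; otherwise the phyletic distances themselves stand in for the
    data vector (zero residual by construction).
    """
    labels, cycle, pairs = read_splits_nexus(path)
    splits = [s for s, _ in pairs]
    weights = np.array([w for _, w in pairs])
    design, _ = build_design_matrix(splits, len(labels))
    dvec = distance_vector(d) if d is not None else design @ weights
    return WeightedSplitSystem(
        splits=tuple(splits), weights=weights, cycle=cycle,
        design=design, dvec=dvec, labels=labels,
    )
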