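"""Group summaries and Mann-Whitney U comparisons of vibratory indices.

Compares normophonic and dysphonic groups on CQ, OQ, SQ and MRGA with the
two-sided Mann-Whitney U test in its plain normal approximation: midranks
over the pooled sample, U = R_x - n_x (n_x + 1) / 2, and

    z = (U - n_x n_y / 2) / sqrt(n_x n_y (n_x + n_y + 1) / 12)

with no continuity and no tie correction, p = 2 Phi(-|z|).  An exact
permutation variant is available for small samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

INDEX_COLUMNS = ("CQ", "OQ", "SQ", "MRGA")
GROUPS = ("normophonic", "dysphonic")


class IndexTable:
    """Per-subject vibratory indices with a group label.

    Backed by a DataFrame with columns
    (subject_id, group, CQ, OQ, SQ, MRGA); subject ids must be unique and
    groups limited to 'normophonic' / 'dysphonic'.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["subject_id", "group", *INDEX_COLUMNS]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        if frame["subject_id"].duplicated().any():
            raise FormatError("subject ids must be unique")
        bad = set(frame["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown groups: {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndexTable":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise FormatError(f"cannot parse index CSV {path}: {exc}") from exc
        if frame.empty:
            raise FormatError(f"index CSV {path} has no rows")
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def values(self, index_name: str, group: str) -> np.ndarray:
        if index_name not in INDEX_COLUMNS:
            raise ParameterError(f"unknown index {index_name!r}")
        if group not in GROUPS:
            raise ParameterError(f"unknown group {group!r}")
        sel = self.frame[self.frame["group"] == group]
        return sel[index_name].to_numpy(dtype=float)


def reference_cohort() -> IndexTable:
    """The packaged 11 + 11 subject reference cohort.

    Vibratory indices published for eleven normophonic subjects (N1-N11)
    and eleven patients with glottal insufficiency (D1-D11); used for
    reproducing the reported group statistics and as a realistic test
    table.
    """
    with resources.files("glottiseg.data").joinpath(
        "reference_cohort.csv"
    ).open() as fh:
        return IndexTable(pd.read_csv(fh))


def group_summary(
    table: IndexTable, index_name: str, group: str, statistic: str = "median"
) -> float:
    """Median or mean of one index within one group.

    The median of an even-sized group is the midpoint of the two central
    order statistics.
    """
    vals = table.values(index_name, group)
    if vals.size == 0:
        raise ParameterError(f"group {group!r} is empty")
    if statistic == "median":
        return float(np.median(vals))
    if statistic == "mean":
        return float(np.mean(vals))
    raise ParameterError(f"statistic must be 'median' or 'mean', got {statistic!r}")


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x from pooled midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))  # midranks
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2)


def mann_whitney_p(x, y, method: str = "normal") -> float:
    """Two-sided Mann-Whitney p-value.

    ``method="normal"`` is the plain large-sample approximation (no
    continuity correction, no tie correction); ``method="exact"``
    enumerates all group assignments of the pooled values and is feasible
    only for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("both groups need at least 2 values")
    u = mann_whitney_u(x, y)
    n_x, n_y = x.size, y.size
    if method == "normal":
        mean = n_x * n_y / 2
        sd = np.sqrt(n_x * n_y * (n_x + n_y + 1) / 12)
        z = (u - mean) / sd
        return float(2 * stats.norm.sf(abs(z)))
    if method == "exact":
        pooled = np.concatenate([x, y])
        n = pooled.size
        total = comb(n, n_x)
        if total > 2_000_000:
            raise ParameterError("exact method infeasible for these sizes")
        dev = abs(u - n_x * n_y / 2)
        hits = 0
        idx = np.arange(n)
        for chosen in combinations(idx, n_x):
            u_p = mann_whitney_u(pooled[list(chosen)], np.delete(pooled, chosen))
            if abs(u_p - n_x * n_y / 2) >= dev - 1e-12:
                hits += 1
        return hits / total
    raise ParameterError(f"unknown method {method!r}")


def p_value_table(table: IndexTable, method: str = "normal") -> pd.Series:
    """Two-sided p-values for all four indices, normophonic vs dysphonic."""
    out = {}
    for name in INDEX_COLUMNS:
        out[name] = mann_whitney_p(
            table.values(name, "normophonic"),
            table.values(name, "dysphonic"),
            method=method,
        )
    return pd.Series(out, name="p_value")


def box_stats(table: IndexTable) -> pd.DataFrame:
    """Q1/median/Q3/min/max per group and index (box-plot statistics)."""
    rows = []
    for group in GROUPS:
        for name in INDEX_COLUMNS:
            vals = table.values(name, group)
            if vals.size == 0:
                continue
            rows.append(
                {
                    "group": group,
                    "index": name,
                    "min": vals.min(),
                    "q1": np.percentile(vals, 25),
                    "median": np.median(vals),
                    "q3": np.percentile(vals, 75),
                    "max": vals.max(),
                    "mean": vals.mean(),
                    "n": vals.size,
                }
            )
    return pd.DataFrame(rows)


def export_report(
    table: IndexTable, out_dir: str | Path, make_figures: bool = True
) -> dict[str, Path]:
    """Write box-plot statistics, p-values, scatter data and figures.

    Returns a name -> path mapping of everything written.  The p-value
    section is omitted (with a warning) when either group is empty.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    stats_df = box_stats(table)
    written["box_stats"] = out / "box_stats.csv"
    stats_df.to_csv(written["box_stats"], index=False)

    written["indices"] = out / "indices.csv"
    table.to_csv(written["indices"])

    both = all(table.values("OQ", g).size > 0 for g in GROUPS)
    if both:
        pvals = p_value_table(table)
        written["p_values"] = out / "p_values.csv"
        pvals.to_frame().to_csv(written["p_values"])
    else:
        log.warning("one group is empty: skipping Mann-Whitney tests")

    digest = hashlib.sha256(
        table.frame.to_csv(index=False).encode()
    ).hexdigest()[:16]
    meta = {"input_sha256_16": digest, "groups": sorted(set(table.frame["group"]))}
    written["meta"] = out / "report_meta.json"
    written["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))

    if make_figures:
        written.update(_figures(table, out, both))
    return written


def _figures(table: IndexTable, out: Path, both: bool) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    fig, axes = plt.subplots(1, 4, figsize=(12, 3.2))
    for ax, name in zip(axes, INDEX_COLUMNS):
        data = [
            table.values(name, g) for g in GROUPS if table.values(name, g).size
        ]
        labels = [g[:4] for g in GROUPS if table.values(name, g).size]
        ax.boxplot(data, tick_labels=labels, whis=(0, 100))
        ax.set_title(name)
    fig.tight_layout()
    written["boxplots"] = out / "boxplots.png"
    fig.savefig(written["boxplots"], dpi=120)
    plt.close(fig)

    if both:
        fig = plt.figure(figsize=(5, 4.5))
        ax = fig.add_subplot(projection="3d")
        for group, color in zip(GROUPS, ("tab:green", "tab:red")):
            ax.scatter(
                table.values("MRGA", group),
                table.values("CQ", group),
                table.values("OQ", group),
                c=color,
                label=group,
            )
        ax.set_xlabel("MRGA")
        ax.set_ylabel("CQ")
        ax.set_zlabel("OQ")
        ax.legend()
        written["scatter3d"] = out / "scatter3d.png"
        fig.savefig(written["scatter3d"], dpi=120)
        plt.close(fig)
    return written
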