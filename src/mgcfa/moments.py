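"""Per-group sufficient statistics (n, mean vector, covariance matrix) and I/O.

Normal-theory maximum likelihood for covariance-structure models needs only
the group sizes, mean vectors, and ML covariance matrices (divisor ``n``,
not ``n - 1``).  This module computes those from person-level tables,
assigns persons to age bins, pools moments across groups, and reads/writes
them in a plain-text ``GCM`` format so deposited moment matrices can stand
in for raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupMoments",
    "GroupingScheme",
    "default_grouping",
    "assign_group",
    "compute_group_moments",
    "pool_moments",
    "read_moments",
    "write_moments",
    "moments_from_arrays",
]


@dataclass
class GroupMoments:
    """Sufficient statistics of one group.

    ``cov`` uses the ML divisor ``n`` so that fitting from moments matches
    raw-data maximum likelihood exactly.
    """

    label: str
    n: int
    mean: np.ndarray
    cov: np.ndarray
    variables: tuple[str, ...]
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.variables)
        if self.mean.shape != (p,):
            raise ValueError(
                f"group {self.label!r}: mean has length {self.mean.shape}, "
                f"expected {p} variables"
            )
        if self.cov.shape != (p, p):
            raise ValueError(
                f"group {self.label!r}: covariance is {self.cov.shape}, expected ({p},{p})"
            )
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError(f"group {self.label!r}: covariance matrix is asymmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)
        if np.any(np.diag(self.cov) < -1e-12):
            raise ValueError(f"group {self.label!r}: negative variance on the diagonal")
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")

    def subset(self, variables: list[str] | tuple[str, ...]) -> "GroupMoments":
        """Moments restricted to (and reordered as) the given variables."""
        idx = [self.variables.index(v) for v in variables]
        return GroupMoments(
            label=self.label,
            n=self.n,
            mean=self.mean[idx],
            cov=self.cov[np.ix_(idx, idx)],
            variables=tuple(variables),
            warnings=self.warnings,
        )


@dataclass(frozen=True)
class GroupingScheme:
    """Ordered age bins (label, lo, hi).

    Integer-labelled brackets like "25-29" cover real ages in [25, 30);
    the last bin is closed at its upper label, so "75-91" covers [75, 91].
    """

    bins: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bins) < 2:
            raise ValueError("a grouping scheme needs at least 2 bins")
        for (l1, _, h1), (l2, lo2, _) in zip(self.bins, self.bins[1:]):
            if lo2 < h1 - 1e-12:
                raise ValueError(f"bins {l1!r} and {l2!r} overlap")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bins)

    def edges(self, i: int) -> tuple[float, float, bool]:
        """(lo, hi, hi_closed) for bin ``i`` on the real-age line."""
        label, lo, hi = self.bins[i]
        last = i == len(self.bins) - 1
        if last:
            return lo, hi, True
        # integer bracket "25-29" means [25, 30)
        return lo, hi + 1.0, False


def default_grouping() -> GroupingScheme:
    """The study's 12 age bins: 18-24, then 5-year bins up to 70-74, then 75-91."""
    bins: list[tuple[str, float, float]] = [("18-24", 18.0, 24.0)]
    for lo in range(25, 75, 5):
        bins.append((f"{lo}-{lo + 4}", float(lo), float(lo + 4)))
    bins.append(("75-91", 75.0, 91.0))
    return GroupingScheme(tuple(bins))


def assign_group(age: float, scheme: GroupingScheme) -> str:
    """Bin label for a real-valued age; raises if outside the scheme's range."""
    for i in range(len(scheme.bins)):
        lo, hi, closed = scheme.edges(i)
        if (lo <= age < hi) or (closed and age == hi):
            return scheme.bins[i][0]
    raise ValueError(f"age {age} is outside the grouping scheme's range")


def moments_from_arrays(
    label: str, x: np.ndarray, variables: tuple[str, ...]
) -> GroupMoments:
    """ML moments (divisor n) of a persons x variables array."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    mean = x.mean(axis=0)
    d = x - mean
    cov = d.T @ d / n
    return GroupMoments(label=label, n=n, mean=mean, cov=cov, variables=variables)


def compute_group_moments(
    table: pd.DataFrame,
    scheme: GroupingScheme,
    items: list[str] | tuple[str, ...],
    age_col: str = "age",
) -> list[GroupMoments]:
    """One :class:`GroupMoments` per bin, persons assigned by age.

    Raises on an empty bin; a bin with ``n < len(items) + 1`` gets a warning
    recorded on its result (too small for estimation use).
    """
    items = tuple(items)
    missing = [c for c in items if c not in table.columns]
    if missing:
        raise KeyError(f"items not in table: {missing}")
    ages = table[age_col].to_numpy(dtype=float)
    labels = np.array([assign_group(a, scheme) for a in ages])
    out: list[GroupMoments] = []
    x_all = table.loc[:, list(items)].to_numpy(dtype=float)
    for lab in scheme.labels:
        mask = labels == lab
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"age bin {lab!r} is empty")
        gm = moments_from_arrays(lab, x_all[mask], items)
        if n < len(items) + 1:
            gm.warnings = (f"group {lab!r}: n={n} < p+1={len(items) + 1}",)
        out.append(gm)
    return out


def pool_moments(groups: list[GroupMoments], label: str = "pooled") -> GroupMoments:
    """Full-sample moments implied by per-group moments.

    Equivalent to concatenating the raw data of all groups: the pooled
    covariance includes the between-group mean dispersion.
    """
    variables = groups[0].variables
    if any(g.variables != variables for g in groups):
        raise ValueError("all groups must share the same variables in the same order")
    n = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n
    cov = sum(g.n * (g.cov + np.outer(g.mean - mean, g.mean - mean)) for g in groups) / n
    return GroupMoments(label=label, n=n, mean=mean, cov=cov, variables=variables)


# ---------------------------------------------------------------------------
# GCM v1 plain-text moment files


def write_moments(path, groups: list[GroupMoments]) -> None:
    """Write moments in GCM v1 format (12 significant digits)."""
    with open(path, "w") as fh:
        fh.write("#GCM 1\n")
        for g in groups:
            fh.write(f"#group {g.label} n={g.n}\n")
            fh.write("#vars " + ",".join(g.variables) + "\n")
            fh.write("means " + ",".join(f"{v:.12g}" for v in g.mean) + "\n")
            for i in range(len(g.variables)):
                row = g.cov[i, : i + 1]
                fh.write(",".join(f"{v:.12g}" for v in row) + "\n")
            fh.write("#end\n")


def read_moments(path, divisor: str = "n") -> list[GroupMoments]:
    """Read a GCM v1 moment file.

    ``divisor="n-1"`` rescales deposited sample covariances (divisor n-1)
    to the ML convention on load.
    """
    if divisor not in ("n", "n-1"):
        raise ValueError("divisor must be 'n' or 'n-1'")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#GCM"):
        raise ValueError("not a GCM file: missing '#GCM' header")
    groups: list[GroupMoments] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("#group"):
            raise ValueError(f"line {i + 1}: expected '#group', got {line!r}")
        head = line.split()
        label = " ".join(head[1:-1])
        if not head[-1].startswith("n="):
            raise ValueError(f"line {i + 1}: missing n= in group header")
        n = int(head[-1][2:])
        i += 1
        if not lines[i].strip().startswith("#vars"):
            raise ValueError(f"line {i + 1}: expected '#vars'")
        variables = tuple(v.strip() for v in lines[i].strip()[5:].split(","))
        p = len(variables)
        i += 1
        if not lines[i].strip().startswith("means"):
            raise ValueError(f"line {i + 1}: expected 'means'")
        mean = np.array([float(v) for v in lines[i].strip()[5:].split(",")])
        if mean.shape != (p,):
            raise ValueError(
                f"line {i + 1}: group {label!r} has {mean.size} means for {p} variables"
            )
        i += 1
        cov = np.zeros((p, p))
        for r in range(p):
            if i >= len(lines) or lines[i].strip().startswith("#"):
                raise ValueError(
                    f"line {i + 1}: group {label!r} has only {r} of {p} covariance rows"
                )
            vals = [float(v) for v in lines[i].strip().split(",")]
            if len(vals) == r + 1:  # lower triangle
                cov[r, : r + 1] = vals
                cov[: r + 1, r] = vals
            elif len(vals) == p:  # full row
                cov[r, :] = vals
            else:
                raise ValueError(
                    f"line {i + 1}: group {label!r} row {r + 1} has {len(vals)} entries"
                )
            i += 1
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError(f"group {label!r}: asymmetric covariance matrix")
        if divisor == "n-1":
            cov = cov * (n - 1) / n
        if i >= len(lines) or lines[i].strip() != "#end":
            raise ValueError(f"line {i + 1}: expected '#end' for group {label!r}")
        i += 1
        groups.append(
            GroupMoments(label=label, n=n, mean=mean, cov=cov, variables=variables)
        )
    return groups
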