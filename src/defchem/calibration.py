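"""Fossil-calibration statistics and calibration-prior transcription.

Two quantities summarize the adequacy of a clade's fossil record for
calibrating divergence times:

* **PenG** (penultimate gap): the interval between the two oldest fossils
  in a clade — a long gap signals a sparse record whose oldest fossil may
  badly underestimate the clade's age.
* **GLin** (ghost lineage length): the difference between the oldest fossil
  ages of two sister lineages — sister clades diverged simultaneously, so
  the younger record implies at least that much unsampled history.

The module also carries transcriptions of two published calibration
schemes for millipede divergence dating (C1: six directly specified node
priors; C2: two lognormal priors whose spreads were derived from PenG/GLin
statistics).  The mapping from (offset, PenG, GLin) to lognormal (mu,
sigma) follows an unpublished procedure, so the C2 entries store the
resulting parameters as printed rather than recomputing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from defchem.errors import ValidationError

__all__ = [
    "FossilTable",
    "CalibrationPrior",
    "peng",
    "glin",
    "read_fossil_table",
    "calibration_stats",
    "emit_calibration_config",
    "read_calibration_config",
    "packaged_calibrations",
]

DISTRIBUTIONS = ("uniform", "lognormal", "lognormal_real_space")


def peng(ages: Sequence[float]) -> float:
    """Penultimate gap: (oldest age) - (second oldest age) within a clade."""
    ages = sorted(float(a) for a in ages)
    if len(ages) < 2:
        raise ValidationError("PenG needs at least 2 fossil ages")
    return ages[-1] - ages[-2]


def glin(oldest_a: float, oldest_b: float) -> float:
    """Ghost lineage length: |oldest_a - oldest_b| for two sister lineages."""
    if oldest_a <= 0 or oldest_b <= 0:
        raise ValidationError("fossil ages must be positive")
    return abs(float(oldest_a) - float(oldest_b))


@dataclass(frozen=True)
class CalibrationPrior:
    """A node-age prior for divergence dating.

    ``distribution`` is one of ``uniform`` (params: lower, upper),
    ``lognormal`` (params: offset, mu, sigma — mu/sigma on the log scale),
    or ``lognormal_real_space`` (params: mean, sigma — mean in real space).
    """

    clade: str
    distribution: str
    params: tuple  # ordered (name, value) pairs
    note: str = ""

    def __post_init__(self):
        p = dict(self.params)
        if self.distribution == "uniform":
            if not {"lower", "upper"} <= p.keys() or not p["lower"] < p["upper"]:
                raise ValidationError(f"{self.clade}: uniform needs lower < upper")
        elif self.distribution == "lognormal":
            if not {"offset", "mu", "sigma"} <= p.keys():
                raise ValidationError(f"{self.clade}: lognormal needs offset, mu, sigma")
            if p["sigma"] <= 0 or p["offset"] < 0:
                raise ValidationError(f"{self.clade}: need sigma > 0 and offset >= 0")
        elif self.distribution == "lognormal_real_space":
            if not {"mean", "sigma"} <= p.keys() or p["sigma"] <= 0:
                raise ValidationError(f"{self.clade}: real-space lognormal needs mean, sigma > 0")
        else:
            raise ValidationError(f"{self.clade}: unknown distribution {self.distribution!r}")

    @staticmethod
    def uniform(clade: str, lower: float, upper: float, note: str = "") -> "CalibrationPrior":
        return CalibrationPrior(clade, "uniform", (("lower", lower), ("upper", upper)), note)

    @staticmethod
    def lognormal(
        clade: str, offset: float, mu: float, sigma: float, note: str = ""
    ) -> "CalibrationPrior":
        return CalibrationPrior(
            clade, "lognormal", (("offset", offset), ("mu", mu), ("sigma", sigma)), note
        )

    @staticmethod
    def lognormal_real_space(
        clade: str, mean: float, sigma: float, note: str = ""
    ) -> "CalibrationPrior":
        return CalibrationPrior(
            clade, "lognormal_real_space", (("mean", mean), ("sigma", sigma)), note
        )


# ---------------------------------------------------------------------------
# fossil tables


class FossilTable:
    """Rows of (clade, fossil, age_ma, lineage) fossil occurrences."""

    def __init__(self, table: pd.DataFrame):
        required = {"clade", "fossil", "age_ma"}
        if not required <= set(table.columns):
            raise ValidationError(f"fossil table needs columns {sorted(required)}")
        if (table["age_ma"] <= 0).any():
            raise ValidationError("fossil ages must be positive")
        if "lineage" not in table.columns:
            table = table.assign(lineage="")
        self.table = table.reset_index(drop=True)

    def clade_ages(self, clade: str) -> list[float]:
        sel = self.table[self.table["clade"] == clade]
        return sorted(sel["age_ma"].tolist())

    def peng(self, clade: str) -> float:
        return peng(self.clade_ages(clade))

    def glin(self, clade: str) -> float:
        """GLin for a clade whose rows carry exactly two lineage tags."""
        sel = self.table[self.table["clade"] == clade]
        tags = [t for t in sel["lineage"].unique() if t]
        if len(tags) != 2:
            raise ValidationError(
                f"GLin for {clade!r} needs exactly two lineage tags, found {tags}"
            )
        oldest = [sel[sel["lineage"] == t]["age_ma"].max() for t in tags]
        return glin(oldest[0], oldest[1])


def read_fossil_table(path: str) -> FossilTable:
    return FossilTable(pd.read_csv(path, sep="\t", comment="#"))


def calibration_stats(fossils: FossilTable) -> pd.DataFrame:
    """Per-clade PenG (and GLin where two lineage tags exist)."""
    rows = []
    for clade in fossils.table["clade"].unique():
        ages = fossils.clade_ages(clade)
        row = {"clade": clade, "n_fossils": len(ages), "oldest_ma": ages[-1]}
        row["peng_ma"] = peng(ages) if len(ages) >= 2 else float("nan")
        try:
            row["glin_ma"] = fossils.glin(clade)
        except ValidationError:
            row["glin_ma"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration config files


def emit_calibration_config(
    scheme: str, priors: Iterable[CalibrationPrior], path: str
) -> None:
    """Write a structured text block per calibrated node.

    The format is line-oriented and round-trips through
    :func:`read_calibration_config`; it is designed to be transformed into
    dating-tool input, not to be one.
    """
    with open(path, "w") as fh:
        fh.write(f"scheme = {scheme}\n")
        for prior in priors:
            fh.write("\n[calibration]\n")
            fh.write(f"clade = {prior.clade}\n")
            fh.write(f"distribution = {prior.distribution}\n")
            for name, value in prior.params:
                fh.write(f"{name} = {value!r}\n")
            if prior.note:
                fh.write(f"note = {prior.note}\n")


def read_calibration_config(path: str) -> tuple[str, list[CalibrationPrior]]:
    scheme = ""
    priors: list[CalibrationPrior] = []
    current: Optional[dict] = None

    def flush():
        nonlocal current
        if current is None:
            return
        params = tuple(
            (k, float(v))
            for k, v in current.items()
            if k not in ("clade", "distribution", "note")
        )
        priors.append(
            CalibrationPrior(
                current.get("clade", ""),
                current.get("distribution", ""),
                params,
                current.get("note", ""),
            )
        )
        current = None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "[calibration]":
                flush()
                current = {}
                continue
            if "=" not in line:
                raise ValidationError(f"unparseable calibration line: {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if current is None:
                if key == "scheme":
                    scheme = value
                continue
            current[key] = value
    flush()
    return scheme, priors


def packaged_calibrations(scheme: str) -> list[CalibrationPrior]:
    """The packaged transcription of the C1 or C2 calibration scheme."""
    if scheme not in ("C1", "C2"):
        raise ValidationError("scheme must be 'C1' or 'C2'")
    path = resources.files("defchem") / "data" / f"calibrations_{scheme.lower()}.txt"
    got_scheme, priors = read_calibration_config(str(path))
    assert got_scheme == scheme
    return priors
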