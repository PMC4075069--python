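"""Hydrogen-to-parent displacement ratios and multiplier tables.

The riding-hydrogen model ties U_iso(H) to the parent atom's U_eq with
a fixed multiplier (1.2 in general, 1.5 for hydroxyl/methyl hydrogens).
These functions compute the actual ratio U_eq-or-iso(H) / U_eq(parent)
per hydrogen, average it over hydrogens sharing a chemical environment,
and tabulate it against temperature, so that temperature-dependent
multipliers can replace the fixed convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_env import group_hydrogens
from .crystal_io import CrystalStructure, DisplacementTensor, u_eq

__all__ = [
    "RatioRecord",
    "RatioTable",
    "hydrogen_ratio",
    "ratio_records",
    "average_by_environment",
    "multiplier_curve",
    "CONVENTIONAL_MULTIPLIERS",
]

#: The fixed riding-model multipliers the temperature-dependent tables
#: are compared against.
CONVENTIONAL_MULTIPLIERS = (1.2, 1.5)


@dataclass(frozen=True)
class RatioRecord:
    """One hydrogen's U(H)/U_eq(parent) ratio at one temperature."""

    h_label: str
    parent_label: str
    environment: str
    temperature: float | None
    ratio: float
    method: str = "observed"       # "observed" | "tls_oniom"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ratio) or self.ratio <= 0:
            raise ValueError(
                f"non-positive or non-finite ratio {self.ratio} for {self.h_label}")


@dataclass
class RatioTable:
    """Per-(environment, temperature) ratio statistics.

    ``frame`` has columns environment, T, mean, sd, n plus the
    deviations of the mean from the conventional 1.2 and 1.5
    multipliers.  sd is the sample standard deviation (0 when n = 1).
    """

    frame: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def row(self, environment: str, temperature: float) -> pd.Series:
        f = self.frame
        sel = f[(f.environment == environment) & (np.isclose(f["T"], temperature))]
        if len(sel) != 1:
            raise KeyError((environment, temperature))
        return sel.iloc[0]


def hydrogen_ratio(structure: CrystalStructure, h_label: str,
                   parent_label: str, environment: str,
                   averaging: str = "arithmetic",
                   method: str = "observed",
                   h_tensor: DisplacementTensor | None = None,
                   parent_tensor: DisplacementTensor | None = None,
                   ) -> RatioRecord | None:
    """Ratio of one hydrogen's U to its parent's U_eq.

    The numerator is U_iso(H) when the hydrogen is isotropic, else the
    equivalent-isotropic value of its tensor with the requested
    averaging; the denominator always uses the same averaging.  Tensors
    may be supplied directly (e.g. TLS+ONIOM predictions) to override
    what the structure carries.  Returns ``None`` (with a warning) when
    displacement data are missing.
    """
    h_atom = structure[h_label]
    try:
        if h_tensor is not None:
            num = u_eq(h_tensor, averaging, label=h_label)
        elif h_atom.u_cif is not None:
            num = u_eq(structure.u_cart(h_label), averaging, label=h_label)
        elif h_atom.u_iso is not None:
            num = h_atom.u_iso
        else:
            warnings.warn(f"hydrogen {h_label} has no displacement data; skipped",
                          stacklevel=2)
            return None
        if parent_tensor is not None:
            den = u_eq(parent_tensor, averaging, label=parent_label)
        else:
            parent = structure[parent_label]
            if not parent.has_adp:
                warnings.warn(f"parent {parent_label} has no displacement data; "
                              f"{h_label} skipped", stacklevel=2)
                return None
            den = u_eq(structure.u_cart(parent_label), averaging, label=parent_label)
    except ValueError as exc:
        warnings.warn(f"{h_label}: {exc}; skipped", stacklevel=2)
        return None
    return RatioRecord(h_label=h_label, parent_label=parent_label,
                       environment=environment, temperature=structure.temperature,
                       ratio=num / den, method=method)


def ratio_records(structure: CrystalStructure,
                  averaging: str = "arithmetic",
                  h_tensors: dict[str, DisplacementTensor] | None = None,
                  method: str = "observed",
                  tolerance: float = 0.40) -> list[RatioRecord]:
    """All hydrogen ratios of one structure, grouped by environment.

    ``h_tensors`` substitutes predicted hydrogen tensors (TLS+ONIOM)
    for the hydrogens' own displacement data.
    """
    records = []
    for env, members in sorted(group_hydrogens(structure, tolerance=tolerance).items()):
        for h_label, parent_label in members:
            rec = hydrogen_ratio(
                structure, h_label, parent_label, env, averaging=averaging,
                method=method,
                h_tensor=None if h_tensors is None else h_tensors.get(h_label))
            if rec is not None:
                records.append(rec)
    return records


def average_by_environment(records: list[RatioRecord]) -> RatioTable:
    """Unweighted mean, sample sd and count per (environment, T)."""
    if not records:
        raise ValueError("no ratio records to average")
    df = pd.DataFrame(
        [(r.environment, r.temperature, r.ratio, r.h_label) for r in records],
        columns=["environment", "T", "ratio", "h_label"],
    )
    # canonical record order => bit-identical tables regardless of input order
    df = df.sort_values(["environment", "T", "h_label", "ratio"]).reset_index(drop=True)
    grouped = (
        df.groupby(["environment", "T"], dropna=False)["ratio"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    grouped["sd"] = grouped["sd"].fillna(0.0)   # n = 1 groups
    for mult in CONVENTIONAL_MULTIPLIERS:
        grouped[f"dev_{mult}"] = grouped["mean"] - mult
    grouped = grouped.sort_values(["environment", "T"]).reset_index(drop=True)
    return RatioTable(frame=grouped)


def multiplier_curve(structures: dict[float, CrystalStructure],
                     temps: list[float] | None = None,
                     averaging: str = "arithmetic",
                     h_tensors: dict[float, dict[str, DisplacementTensor]] | None = None,
                     method: str = "observed") -> RatioTable:
    """Ratio-vs-temperature table from one structure per temperature.

    ``structures`` maps T (K) to the structure refined (or simulated)
    at that temperature; ``h_tensors`` optionally maps T to predicted
    hydrogen tensors (the TLS+ONIOM route).  Temperatures requested but
    not supplied are skipped with a warning.
    """
    if temps is None:
        temps = sorted(structures)
    records: list[RatioRecord] = []
    for t in temps:
        if t not in structures:
            warnings.warn(f"no structure at T = {t} K; row omitted", stacklevel=2)
            continue
        s = structures[t]
        if s.temperature is None:
            s.temperature = t
        records.extend(ratio_records(
            s, averaging=averaging,
            h_tensors=None if h_tensors is None else h_tensors.get(t),
            method=method))
    return average_by_environment(records)
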