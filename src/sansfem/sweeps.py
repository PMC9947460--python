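"""Sweep drivers for the sensitivity studies and the baseline table.

Every driver returns a :class:`SweepResult` whose long-format table has one
row per (case, swelling state) with the full biometric report.  Failed cells
are recorded with their diagnostics rather than aborting the sweep, and a
cache directory makes sweeps resumable (cells keyed by a provenance hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import AnatomyParams, preset_case
from .constitutive import default_tissues, with_modulus
from .loads import LoadCase, TABLE2_SCHEDULE
from .protocol import ProtocolResult, StageError, run_protocol

log = logging.getLogger("sansfem.sweeps")

TABLE2_COLUMNS = ["eps_H_fat", "J_H_fat", "proptosis_mm",
                  "delta_axial_length_um", "delta_arc_um", "delta_roc_mm"]


@dataclass
class SweepResult:
    name: str
    table: pd.DataFrame
    failures: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        return pd.read_csv(path)


def _provenance(kind: str, **kw) -> str:
    blob = json.dumps({"kind": kind, **{k: repr(v) for k, v in kw.items()}},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cached_run(cache_dir, key, fn):
    if cache_dir is not None:
        f = Path(cache_dir) / f"{key}.json"
        if f.exists():
            return pd.DataFrame(json.loads(f.read_text())), None
    try:
        result: ProtocolResult = fn()
    except (StageError, Exception) as exc:   # noqa: BLE001 - recorded, not lost
        return None, exc
    df = result.table()
    df["case"] = result.case_name
    df["max_F_EOM_mN"] = result.max_F_EOM_mN
    df["g_v_um"] = result.zero_stress.g_v_um
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"{key}.json").write_text(
            df.to_json(orient="records"))
    return df, None


def run_table2(density="coarse", order=2, cache_dir=None,
               schedule=TABLE2_SCHEDULE) -> SweepResult:
    """Baseline swelling table: one row per schedule point."""
    key = _provenance("table2", density=density, order=order,
                      schedule=tuple(schedule))
    lc = LoadCase(eps_H_fat=list(schedule))
    df, err = _cached_run(cache_dir, key, lambda: run_protocol(
        "baseline", load_case=lc, density=density, order=order))
    if err is not None:
        raise err
    return SweepResult("table2", df, meta={"provenance": key,
                                           "density": density})


def run_icp_grid(icp_values, eps_values, density="coarse", order=2,
                 cache_dir=None) -> SweepResult:
    """Full factorial ICP x fat-swelling grid.

    Each ICP value is reached by ramping ICP together with the swelling
    (proportional loading); rows at eps = 0 keep the terrestrial ICP path.
    """
    frames, fails = [], []
    for icp in icp_values:
        lc = LoadCase(eps_H_fat=sorted(set([0.0] + list(eps_values))))
        key = _provenance("icp", icp=icp, eps=tuple(lc.eps_H_fat),
                          density=density, order=order)
        df, err = _cached_run(cache_dir, key, lambda icp=icp, lc=lc: run_protocol(
            "baseline", load_case=lc, density=density, order=order,
            icp_final_cmH2O=icp))
        if err is not None:
            fails.append({"icp": icp, "error": str(err)})
            continue
        df = df[df.eps_H_fat.isin(eps_values)].copy()
        df["ICP_cmH2O"] = np.where(df.eps_H_fat > 0, icp, 13.6)
        df.loc[df.eps_H_fat == df.eps_H_fat.max(), "ICP_cmH2O"] = icp
        df["ICP_target_cmH2O"] = icp
        frames.append(df)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    # effect-size summary: range over ICP at max swelling vs range over
    # swelling at the baseline ICP path
    meta = {}
    if len(frames) > 1:
        eps_max = max(eps_values)
        at_max = table[table.eps_H_fat == eps_max]
        meta["range_over_icp_um"] = float(
            at_max.delta_axial_length_um.max()
            - at_max.delta_axial_length_um.min())
        one = frames[0]
        meta["range_over_swelling_um"] = float(
            one.delta_axial_length_um.max() - one.delta_axial_length_um.min())
    return SweepResult("icp_grid", table, fails, meta)


def run_anatomy_sensitivity(eps_level=0.07, density="coarse", order=2,
                            cache_dir=None, schedule=None) -> SweepResult:
    """+10% single-parameter anatomical perturbations vs baseline."""
    cases = ["baseline", "plus10_RP", "plus10_REq", "plus10_LO",
             "plus10_ROM", "plus10_LOM"]
    sched = schedule if schedule is not None else [0.0, eps_level / 2,
                                                   eps_level]
    frames, fails = [], []
    for case in cases:
        lc_base = preset_case(case)[2]
        lc = LoadCase(ICP=lc_base.ICP, M=lc_base.M, eps_H_fat=list(sched))
        key = _provenance("anat", case=case, sched=tuple(sched),
                          density=density, order=order)
        df, err = _cached_run(cache_dir, key, lambda case=case, lc=lc:
                              run_protocol(case, load_case=lc,
                                           density=density, order=order))
        if err is not None:
            fails.append({"case": case, "error": str(err)})
            continue
        frames.append(df)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return SweepResult("anatomy", table, fails,
                       meta={"eps_level": eps_level})


def run_stiffness_sweep(E_sclera_MPa=(0.25, 0.5, 1.5, 5.0),
                        E_fat_Pa=(700.0, 1500.0),
                        E_vitreous_Pa=(6.5, 25.0),
                        eps_level=0.07, density="coarse", order=2,
                        cache_dir=None, schedule=None) -> SweepResult:
    """Elastic-modulus sweeps: sclera (strong effect expected), fat and
    vitreous (null effect expected)."""
    sched = schedule if schedule is not None else [0.0, eps_level / 2,
                                                   eps_level]
    frames, fails = [], []

    def one(tag, tissue, E):
        tis = with_modulus(default_tissues(), tissue, E)
        lc = LoadCase(eps_H_fat=list(sched))
        key = _provenance("stiff", tissue=tissue, E=E, sched=tuple(sched),
                          density=density, order=order)
        df, err = _cached_run(cache_dir, key, lambda: run_protocol(
            "baseline", tissues=tis, load_case=lc, density=density,
            order=order))
        if err is not None:
            fails.append({"case": tag, "error": str(err)})
            return
        df["tissue"] = tissue
        df["E_Pa"] = E
        df["case"] = tag
        frames.append(df)

    for E in E_sclera_MPa:
        one(f"sclera_{E}MPa", "ocular_coats", E * 1e6)
    for E in E_fat_Pa:
        one(f"fat_{E}Pa", "orbital_fat", E)
    for E in E_vitreous_Pa:
        one(f"vitreous_{E}Pa", "vitreous", E)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return SweepResult("stiffness", table, fails)
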