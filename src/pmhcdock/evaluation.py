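"""Cross-docking evaluation: MHC-superposed epitope RMSD and benchmark stats.

A model complex is judged against its reference crystal by superposing the
MHC chains (Calpha of shared heavy-chain residues, plus beta-2-microglobulin
when both structures carry one) and measuring the epitope's RMSD — over
Calpha atoms and over all heavy atoms — so the score captures both the
epitope's internal conformation and its placement in the cleft. A model
counts as an accurate reproduction when its Calpha RMSD is 2.0 A or less
(non-strict). Benchmark runs aggregate per-(allotype, length) statistics:
n, mean, sample s.d., s.e.m., median and interquartile range, plus a pooled
TOTAL row whose mean is exactly the count-weighted mean of the group means.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StructureError
from .geometry import kabsch_superpose
from .structure_io import (ChainRoles, Structure, assign_chain_roles,
                           read_pdb, sanitize_structure, select_atom_records,
                           Selection)

RMSD_PASS_CUTOFF = 2.0  # Angstrom, on the epitope Calpha RMSD


@dataclasses.dataclass(frozen=True)
class EvaluationRecord:
    model_id: str
    target_id: str
    allotype: str
    epitope_length: int
    rmsd_ca: float
    rmsd_all: float
    passed_2A: bool
    n_all_atoms: int = 0  # heavy atoms actually compared (after pair-dropping)

    @classmethod
    def from_rmsds(cls, model_id, target_id, allotype, epitope_length,
                   rmsd_ca, rmsd_all, n_all_atoms=0):
        return cls(model_id=model_id, target_id=target_id, allotype=allotype,
                   epitope_length=epitope_length,
                   rmsd_ca=float(rmsd_ca), rmsd_all=float(rmsd_all),
                   passed_2A=bool(rmsd_ca <= RMSD_PASS_CUTOFF),
                   n_all_atoms=n_all_atoms)


def _mhc_fit_pairs(model: Structure, target: Structure,
                   roles_m: ChainRoles, roles_t: ChainRoles
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Corresponding MHC Calpha coordinates matched by residue number."""
    pairs_m, pairs_t = [], []
    chain_pairs = [(roles_m.heavy_chain, roles_t.heavy_chain)]
    if roles_m.beta2m is not None and roles_t.beta2m is not None:
        chain_pairs.append((roles_m.beta2m, roles_t.beta2m))
    for cm, ct in chain_pairs:
        target_ca = {
            (r.number, r.insertion_code): r.atom("CA")
            for r in target.chain_residues(ct) if r.atom("CA") is not None}
        for r in model.chain_residues(cm):
            ca = r.atom("CA")
            other = target_ca.get((r.number, r.insertion_code))
            if ca is not None and other is not None:
                pairs_m.append(ca.coords)
                pairs_t.append(other.coords)
    if len(pairs_m) < 3:
        raise StructureError(
            f"only {len(pairs_m)} shared MHC Calpha atoms; cannot superpose")
    return np.array(pairs_m), np.array(pairs_t)


def _peptide_pairs(model: Structure, target: Structure,
                   roles_m: ChainRoles, roles_t: ChainRoles,
                   atom_class: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Epitope atom pairs matched by residue position and atom name.

    Atoms missing on either side (crystal disorder) are dropped pairwise;
    the count of compared atoms is returned alongside the coordinates.
    """
    sel = Selection(atom_class=atom_class, target="peptide")
    wanted_m = set(id(a) for a in select_atom_records(model, sel, roles_m))
    wanted_t = set(id(a) for a in select_atom_records(target, sel, roles_t))
    res_m = {}
    for pos, res in enumerate(model.chain_residues(roles_m.peptide)):
        for a in res.atoms:
            if id(a) in wanted_m:
                res_m[(pos, a.name)] = a
    res_t = {}
    for pos, res in enumerate(target.chain_residues(roles_t.peptide)):
        for a in res.atoms:
            if id(a) in wanted_t:
                res_t[(pos, a.name)] = a
    shared = sorted(set(res_m) & set(res_t))
    if not shared:
        raise StructureError("no shared epitope atoms to compare")
    xm = np.array([res_m[k].coords for k in shared])
    xt = np.array([res_t[k].coords for k in shared])
    return xm, xt, len(shared)


def evaluate_model(model: Structure, target: Structure,
                   model_id: str = "model", target_id: str = "target",
                   allotype: str = "", epitope_length: int | None = None
                   ) -> EvaluationRecord:
    """MHC-superposed epitope RMSD of a modelled complex vs its reference.

    Both structures must be sanitized with assignable chain roles and equal
    peptide sequences. The rigid fit is computed on shared MHC Calpha atoms
    and applied to the model; the epitope RMSD is then measured without any
    further fitting, so translation/rotation of the peptide inside the cleft
    counts toward the score.
    """
    roles_m = assign_chain_roles(model)
    roles_t = assign_chain_roles(target)
    seq_m = model.sequence(roles_m.peptide)
    seq_t = target.sequence(roles_t.peptide)
    if seq_m != seq_t:
        raise StructureError(
            f"peptide sequences differ: model {seq_m!r} vs target {seq_t!r}")
    fit_m, fit_t = _mhc_fit_pairs(model, target, roles_m, roles_t)
    transform, _ = kabsch_superpose(fit_m, fit_t)
    fitted = model.transformed(transform.rotation, transform.translation)

    ca_m, ca_t, _ = _peptide_pairs(fitted, target, roles_m, roles_t, "CA")
    all_m, all_t, n_all = _peptide_pairs(fitted, target, roles_m, roles_t,
                                         "heavy")
    rmsd_ca = float(np.sqrt(np.mean(np.sum((ca_m - ca_t) ** 2, axis=1))))
    rmsd_all = float(np.sqrt(np.mean(np.sum((all_m - all_t) ** 2, axis=1))))
    return EvaluationRecord.from_rmsds(
        model_id, target_id, allotype or "", epitope_length or len(seq_m),
        rmsd_ca, rmsd_all, n_all_atoms=n_all)


# ---------------------------------------------------------------------------
# aggregation

_METRICS = {"ca": "rmsd_ca", "all": "rmsd_all"}


def _group_stats(values: np.ndarray) -> dict:
    n = len(values)
    out = {"mean": float(np.mean(values)),
           "median": float(np.median(values)),
           "q25": float(np.percentile(values, 25)),
           "q75": float(np.percentile(values, 75))}
    if n > 1:
        sd = float(np.std(values, ddof=1))
        out["sd"] = sd
        out["sem"] = sd / math.sqrt(n)
    else:
        out["sd"] = float("nan")
        out["sem"] = float("nan")
    return out


@dataclasses.dataclass
class StatsTable:
    """Per-(allotype, epitope length) RMSD statistics plus a pooled TOTAL."""
    frame: pd.DataFrame

    def total_row(self) -> pd.Series:
        return self.frame[self.frame["allotype"] == "TOTAL"].iloc[0]

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        out = self.frame.copy()
        num = out.select_dtypes(include=[float]).columns
        out[num] = out[num].round(decimals)
        return out

    def to_csv(self, path, decimals: int = 3) -> None:
        self.rounded(decimals).to_csv(path, index=False)

    def to_json(self, decimals: int = 3) -> str:
        return self.rounded(decimals).to_json(orient="records")


def aggregate_stats(records: list[EvaluationRecord]) -> StatsTable:
    """Group records by (allotype, epitope length) and pool a TOTAL row.

    The TOTAL mean over all records equals the count-weighted mean of the
    group means exactly, because both are computed from the same values.
    """
    if not records:
        raise StructureError("no evaluation records to aggregate")
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    rows = []
    for (allotype, length), group in df.groupby(
            ["allotype", "epitope_length"], sort=True):
        row = {"allotype": allotype, "epitope_length": int(length),
               "n": int(len(group)),
               "n_passed_2A": int(group["passed_2A"].sum())}
        for prefix, col in _METRICS.items():
            for stat, value in _group_stats(group[col].to_numpy()).items():
                row[f"{prefix}_{stat}"] = value
        rows.append(row)
    total = {"allotype": "TOTAL", "epitope_length": 0, "n": int(len(df)),
             "n_passed_2A": int(df["passed_2A"].sum())}
    for prefix, col in _METRICS.items():
        for stat, value in _group_stats(df[col].to_numpy()).items():
            total[f"{prefix}_{stat}"] = value
    rows.append(total)
    return StatsTable(frame=pd.DataFrame(rows))


def pooled_mean(counts, means) -> float:
    """Count-weighted mean of group means — the TOTAL-row identity."""
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    return float(np.sum(counts * means) / np.sum(counts))


def summarize_group_table(groups: list[dict]) -> dict:
    """Pool published per-group summaries (n, means, sds) into totals.

    Input rows carry ``n``, ``ca_mean``, ``ca_sd``, ``all_mean``, ``all_sd``;
    the output reports the summed count, the count-weighted total means and
    each group's s.e.m. recovered as sd/sqrt(n).
    """
    ns = [g["n"] for g in groups]
    out = {
        "n": int(sum(ns)),
        "ca_mean": pooled_mean(ns, [g["ca_mean"] for g in groups]),
        "all_mean": pooled_mean(ns, [g["all_mean"] for g in groups]),
        "groups": [],
    }
    for g in groups:
        out["groups"].append({
            "allotype": g["allotype"],
            "epitope_length": g["epitope_length"],
            "ca_sem": g["ca_sd"] / math.sqrt(g["n"]),
            "all_sem": g["all_sd"] / math.sqrt(g["n"]),
        })
    return out


# ---------------------------------------------------------------------------
# benchmark harness

def benchmark(manifest_path: str | Path, out_dir: str | Path | None = None,
              pipeline_config=None, seed: int = 0
              ) -> tuple[pd.DataFrame, StatsTable, list[dict]]:
    """Evaluate model/target pairs listed in a manifest CSV.

    Manifest columns: ``model_path,target_path,allotype,epitope_length``
    (header required). A row may instead carry a ``sequence`` with an empty
    ``model_path``, in which case the model is produced by running the
    modelling pipeline (``pipeline_config`` required). Failing rows are
    recorded and skipped; the run continues.

    Returns (records dataframe, stats table, skipped rows). With ``out_dir``
    set, writes ``records.csv`` and ``stats.csv``.
    """
    manifest = pd.read_csv(manifest_path)
    required = {"model_path", "target_path", "allotype", "epitope_length"}
    missing = required - set(manifest.columns)
    if missing:
        raise StructureError(f"manifest missing columns: {sorted(missing)}")
    base = Path(manifest_path).parent
    records: list[EvaluationRecord] = []
    skipped: list[dict] = []
    for idx, row in manifest.iterrows():
        try:
            target = sanitize_structure(read_pdb(_resolve(base, row["target_path"])))
            model_path = row.get("model_path", "")
            if isinstance(model_path, str) and model_path.strip():
                model = sanitize_structure(read_pdb(_resolve(base, model_path)))
                model_id = Path(model_path).stem
            else:
                from .pipeline import model_pmhc
                if pipeline_config is None:
                    raise StructureError(
                        "manifest row requests a pipeline run but no "
                        "pipeline config was given")
                run = model_pmhc(str(row["sequence"]), str(row["allotype"]),
                                 pipeline_config, seed=seed + int(idx))
                if run.status != "finalized":
                    raise StructureError(
                        f"pipeline aborted: {run.stage_log[-1]}")
                model = run.final_complex
                model_id = f"pipeline:{row['sequence']}"
            records.append(evaluate_model(
                model, target, model_id=model_id,
                target_id=Path(str(row["target_path"])).stem,
                allotype=str(row["allotype"]),
                epitope_length=int(row["epitope_length"])))
        except (OSError, Exception) as exc:  # noqa: BLE001 - per-row isolation
            skipped.append({"row": int(idx), "reason": str(exc)})
    if not records:
        raise StructureError(
            f"no manifest row could be evaluated ({len(skipped)} skipped)")
    records_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    stats = aggregate_stats(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records_df.round(3).to_csv(out_dir / "records.csv", index=False)
        stats.to_csv(out_dir / "stats.csv")
    return records_df, stats, skipped


def _resolve(base: Path, p) -> Path:
    p = Path(str(p))
    return p if p.is_absolute() else base / p
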