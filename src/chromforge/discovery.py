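"""Cross-run component discovery: catalog, assignment and diagnostics.

Components extracted run by run are correlated into a catalog of unique
sample components.  A component that eluted pure (alone in its cluster) in
at least one run seeds or joins a catalog entry; entries are merged when
their unit-normalized UV spectra correlate at or above the acceptance limit
(Pearson r >= 0.95 by default) — unless MS evidence says otherwise: two
spectra with matching UV but different MS base peaks stay separate entries.

Each catalog entry is then assigned a retention time in every run by
matching it (greedy, descending correlation, one-to-one per run) to the
best-correlating extracted component.  A best correlation that is
significant but below the limit (0.8 < r < 0.95) leaves the cell unassigned
with an alert flag: these cells demand chromatographer review, and retention
fitting refuses to proceed over unresolved alerts unless explicitly waived.

Diagnostics surface the classic false-positive patterns: redundant entry
pairs (same spectrum, same retention everywhere), "sum spectrum" artifacts
(an entry matching the sum of two fully co-eluting entries), and
per-column inconsistency (assignable on one column, never on another).
All diagnostics are advisory; nothing is auto-deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .chromio import Chromatogram
from .clusters import PeakCluster, segment_chromatogram
from .mcr import ExtractedComponent, resolve_cluster

__all__ = [
    "CatalogEntry",
    "ComponentCatalog",
    "CellFlag",
    "AssignmentTable",
    "build_catalog",
    "assign",
    "background_filter",
    "diagnostics",
    "resolve",
    "UnresolvedAlertError",
    "discover",
    "spectral_r",
    "ms_cosine",
]

THR_UV_DEFAULT = 0.95
ALERT_FLOOR_DEFAULT = 0.8
THR_MS_COSINE_DEFAULT = 0.9


def spectral_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two spectra on the common channel grid."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def ms_cosine(
    a: dict[float, float], b: dict[float, float], bin_width: float = 1.0
) -> float:
    """Cosine similarity of two sparse MS spectra on matched integer bins."""
    bins_a = {round(mz / bin_width): v for mz, v in a.items()}
    bins_b = {round(mz / bin_width): v for mz, v in b.items()}
    keys = set(bins_a) | set(bins_b)
    va = np.array([bins_a.get(k, 0.0) for k in keys])
    vb = np.array([bins_b.get(k, 0.0) for k in keys])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def _base_peak(ms: dict[float, float] | None) -> float | None:
    if not ms:
        return None
    return max(ms, key=ms.get)


@dataclass
class CatalogEntry:
    entry_id: int
    spectrum: np.ndarray  # consensus, unit Euclidean norm
    members: list[ExtractedComponent] = field(default_factory=list)
    ms_spectrum: dict[float, float] | None = None
    origin: str = "pure"  # "pure" | "mixed"
    artifact: bool = False
    artifact_r: float = 0.0

    @property
    def provenance_runs(self) -> list[str]:
        return sorted({m.run_id for m in self.members})

    @property
    def base_peak(self) -> float | None:
        return _base_peak(self.ms_spectrum)


@dataclass
class ComponentCatalog:
    pure_set: list[CatalogEntry]
    mixed_set: list[ExtractedComponent]
    correlation_threshold_uv: float = THR_UV_DEFAULT
    alert_floor: float = ALERT_FLOOR_DEFAULT

    @property
    def active_entries(self) -> list[CatalogEntry]:
        """Entries that enter modelling (artifact-flagged ones excluded)."""
        return [e for e in self.pure_set if not e.artifact]

    def entry(self, entry_id: int) -> CatalogEntry:
        for e in self.pure_set:
            if e.entry_id == entry_id:
                return e
        raise KeyError(f"no catalog entry {entry_id}")


class CellFlag(str, Enum):
    assigned = "assigned"
    alert = "alert"
    unassigned = "unassigned"
    manual = "manual"


@dataclass
class Cell:
    tR: float | None
    flag: CellFlag
    best_r: float


@dataclass
class AssignmentTable:
    """Retention times of catalog entries across runs, with alert flags."""

    entries: list[int]  # catalog entry ids (rows)
    run_ids: list[str]  # columns
    cells: dict[tuple[int, str], Cell]

    def cell(self, entry_id: int, run_id: str) -> Cell:
        return self.cells[(entry_id, run_id)]

    def tR_row(self, entry_id: int) -> dict[str, float]:
        out = {}
        for rid in self.run_ids:
            c = self.cells[(entry_id, rid)]
            if c.flag in (CellFlag.assigned, CellFlag.manual) and c.tR is not None:
                out[rid] = c.tR
        return out

    def alert_cells(self) -> list[tuple[int, str]]:
        return [k for k, c in self.cells.items() if c.flag is CellFlag.alert]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eid in self.entries:
            for rid in self.run_ids:
                c = self.cells[(eid, rid)]
                rows.append(
                    {
                        "entry": eid,
                        "run_id": rid,
                        "tR": c.tR,
                        "flag": c.flag.value,
                        "best_r": c.best_r,
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


class UnresolvedAlertError(RuntimeError):
    """Raised when model fitting is attempted over outstanding alert cells."""


# ---------------------------------------------------------------------------
# catalog construction


def build_catalog(
    extracted: list[ExtractedComponent],
    thr_uv: float = THR_UV_DEFAULT,
    alert_floor: float = ALERT_FLOOR_DEFAULT,
    ms_mode: bool = False,
    thr_ms: float = THR_MS_COSINE_DEFAULT,
) -> ComponentCatalog:
    """Merge pure-eluting extracted components into unique catalog entries.

    Components flagged pure are processed in order of decreasing purity; one
    joins an existing entry when the UV spectral correlation reaches
    ``thr_uv`` and, in ``ms_mode``, the MS base peaks do not disagree.  The
    consensus spectrum is the renormalized mean of the members.  Components
    never pure anywhere form the mixed set.
    """
    pure = sorted(
        (c for c in extracted if c.pure), key=lambda c: -c.purity
    )
    mixed = [c for c in extracted if not c.pure]
    entries: list[CatalogEntry] = []
    next_id = 1
    for comp in pure:
        target = None
        for entry in entries:
            r = spectral_r(entry.spectrum, comp.spectrum)
            if r >= thr_uv:
                if ms_mode and entry.ms_spectrum and comp.ms_spectrum:
                    bp_e, bp_c = entry.base_peak, _base_peak(comp.ms_spectrum)
                    if bp_e is not None and bp_c is not None and abs(bp_e - bp_c) > 0.5:
                        continue  # identical UV, different MS: keep separate
                    if ms_cosine(entry.ms_spectrum, comp.ms_spectrum) < thr_ms:
                        continue
                target = entry
                break
        if target is None:
            entries.append(
                CatalogEntry(
                    entry_id=next_id,
                    spectrum=comp.spectrum.copy(),
                    members=[comp],
                    ms_spectrum=comp.ms_spectrum,
                )
            )
            next_id += 1
        else:
            target.members.append(comp)
            mean = np.mean([m.spectrum for m in target.members], axis=0)
            target.spectrum = mean / np.linalg.norm(mean)
    return ComponentCatalog(entries, mixed, thr_uv, alert_floor)


# ---------------------------------------------------------------------------
# assignment


def assign(
    catalog: ComponentCatalog,
    extracted_per_run: dict[str, list[ExtractedComponent]],
    thr_uv: float | None = None,
    alert_floor: float | None = None,
) -> AssignmentTable:
    """Assign every active catalog entry a retention time in every run.

    Per run, candidate (entry, component) pairs are ranked by descending
    spectral correlation and matched greedily one-to-one; ties within 1e-9
    go to the candidate closer to the entry's median already-assigned
    retention time.  r >= thr assigns; alert_floor < r < thr issues an alert
    and leaves the cell unassigned.  After this pure pass, mixed-set spectra
    are merged into provisional entries and matched against the still
    unconsumed components under the same limits.
    """
    thr = catalog.correlation_threshold_uv if thr_uv is None else thr_uv
    floor = catalog.alert_floor if alert_floor is None else alert_floor
    run_ids = sorted(extracted_per_run)

    # second pass: fold never-pure (mixed-set) spectra into provisional
    # entries; keep only those not already represented in the pure set
    _mixed_pass(catalog, thr)

    entries = catalog.active_entries
    cells: dict[tuple[int, str], Cell] = {}
    consumed: dict[str, set[int]] = {rid: set() for rid in run_ids}
    median_tR: dict[int, float] = {}

    for rid in run_ids:
        comps = extracted_per_run[rid]
        R = np.zeros((len(entries), len(comps)))
        for ei, entry in enumerate(entries):
            for ci, comp in enumerate(comps):
                R[ei, ci] = spectral_r(entry.spectrum, comp.spectrum)
        best_r = R.max(axis=1) if len(comps) else np.zeros(len(entries))

        cand = [
            (R[ei, ci], ei, ci)
            for ei in range(len(entries))
            for ci in range(len(comps))
            if R[ei, ci] > floor
        ]

        def sort_key(item: tuple[float, int, int]) -> tuple[float, float]:
            r, ei, ci = item
            med = median_tR.get(entries[ei].entry_id)
            dtr = abs(comps[ci].apex_time - med) if med is not None else 0.0
            # quantize r so equal-within-1e-9 candidates fall back to dtR
            return (-round(r / 1e-9) * 1e-9, dtr)

        cand.sort(key=sort_key)
        taken_entries: set[int] = set()
        for r, ei, ci in cand:
            if ei in taken_entries or ci in consumed[rid]:
                continue
            eid = entries[ei].entry_id
            if r >= thr:
                cells[(eid, rid)] = Cell(comps[ci].apex_time, CellFlag.assigned, r)
                consumed[rid].add(ci)
            else:
                cells[(eid, rid)] = Cell(None, CellFlag.alert, r)
            taken_entries.add(ei)
        for ei, entry in enumerate(entries):
            cells.setdefault(
                (entry.entry_id, rid),
                Cell(None, CellFlag.unassigned, float(best_r[ei])),
            )
        for entry in entries:
            tRs = [
                c.tR
                for (eid2, _), c in cells.items()
                if eid2 == entry.entry_id and c.tR is not None
            ]
            if tRs:
                median_tR[entry.entry_id] = float(np.median(tRs))

    return AssignmentTable(
        entries=[e.entry_id for e in entries], run_ids=run_ids, cells=cells
    )


def _mixed_pass(
    catalog: ComponentCatalog,
    thr: float,
    min_runs: int = 2,
    dtr_tol: float = 0.01,
) -> None:
    """Promote never-pure spectra unexplained by the pure set to provisional
    catalog entries (origin "mixed").

    A real component's resolved spectrum recurs across runs, so promotion
    requires the merged group to span at least ``min_runs`` distinct runs.
    It must also carry new spectral information: a candidate whose spectrum
    is reproduced (r >= thr) by a non-negative combination of the spectra of
    catalog entries it co-elutes with is a deformed or summed co-extraction
    of peaks already in the catalog — the classic false positive — and stays
    in the mixed set for reporting only.
    """
    provisional: list[CatalogEntry] = []
    next_id = max((e.entry_id for e in catalog.pure_set), default=0) + 1
    for comp in sorted(catalog.mixed_set, key=lambda c: -c.purity):
        if any(
            spectral_r(e.spectrum, comp.spectrum) >= thr for e in catalog.pure_set
        ):
            continue
        target = None
        for entry in provisional:
            if spectral_r(entry.spectrum, comp.spectrum) >= thr:
                target = entry
                break
        if target is None:
            provisional.append(
                CatalogEntry(
                    entry_id=next_id,
                    spectrum=comp.spectrum.copy(),
                    members=[comp],
                    ms_spectrum=comp.ms_spectrum,
                    origin="mixed",
                )
            )
            next_id += 1
        else:
            target.members.append(comp)
            mean = np.mean([m.spectrum for m in target.members], axis=0)
            target.spectrum = mean / np.linalg.norm(mean)
    from scipy.optimize import nnls as _nnls

    coelute_window = max(dtr_tol, 0.2)  # a few peak widths, minutes

    def _explained(entry: CatalogEntry) -> bool:
        coeluting = [
            pe
            for pe in catalog.pure_set
            if any(
                pm.run_id == m.run_id
                and abs(pm.apex_time - m.apex_time) <= coelute_window
                for pm in pe.members
                for m in entry.members
            )
        ]
        if not coeluting:
            return False
        A = np.column_stack([pe.spectrum for pe in coeluting])
        coef, _ = _nnls(A, entry.spectrum)
        recon = A @ coef
        return spectral_r(entry.spectrum, recon) >= thr

    kept = [
        e
        for e in provisional
        if len(e.provenance_runs) >= min_runs and not _explained(e)
    ]
    for new_id, e in enumerate(kept, start=max((x.entry_id for x in catalog.pure_set), default=0) + 1):
        e.entry_id = new_id
    catalog.pure_set.extend(kept)


# ---------------------------------------------------------------------------
# background / artifact filtering


def background_filter(
    catalog: ComponentCatalog,
    runs: list[Chromatogram],
    clusters_per_run: dict[str, list[PeakCluster]] | None = None,
    thr: float = 0.95,
) -> ComponentCatalog:
    """Flag catalog entries whose spectrum tracks a run's background.

    The background spectrum of a run is the mean spectrum over its baseline
    points (everything outside detected clusters).  An entry correlating with
    any background at |r| >= ``thr`` — positively or negatively — is flagged
    as an artifact and excluded from modelling, never deleted.
    """
    backgrounds: list[np.ndarray] = []
    for chrom in runs:
        if clusters_per_run is not None and chrom.run_id in clusters_per_run:
            cls = clusters_per_run[chrom.run_id]
        else:
            cls = segment_chromatogram(chrom)
        mask = np.ones(chrom.time.size, dtype=bool)
        for cl in cls:
            mask[cl.i_start : cl.i_end] = False
        if mask.sum() < 3:
            continue
        bg = chrom.intensity[mask].mean(axis=0)
        if np.std(bg) > 0:
            backgrounds.append(bg)
    for entry in catalog.pure_set:
        for bg in backgrounds:
            r = spectral_r(entry.spectrum, bg)
            if abs(r) >= thr:
                entry.artifact = True
                entry.artifact_r = r
                break
    return catalog


# ---------------------------------------------------------------------------
# diagnostics


def diagnostics(
    table: AssignmentTable,
    catalog: ComponentCatalog,
    thr: float | None = None,
    dtr_tol: float | None = None,
    sampling_interval: float = 1.0 / 300.0,
    column_of_run: dict[str, str] | None = None,
) -> dict:
    """Advisory false-positive report.

    * redundancy: entry pairs with spectral r >= thr whose assigned retention
      times agree within ``dtr_tol`` in every co-assigned run;
    * sum-spectrum: an entry whose spectrum matches the normalized sum of two
      other entries that co-elute (assigned within ``dtr_tol``) in some run;
    * column inconsistency: entries assigned in every run of one column but
      never assigned on another column.
    """
    thr = catalog.correlation_threshold_uv if thr is None else thr
    tol = 2.0 * sampling_interval if dtr_tol is None else dtr_tol
    entries = catalog.active_entries
    report: dict = {"redundancy": [], "sum_spectrum": [], "column_inconsistency": []}

    rows = {e.entry_id: table.tR_row(e.entry_id) for e in entries}

    for i, ei in enumerate(entries):
        for ej in entries[i + 1 :]:
            r = spectral_r(ei.spectrum, ej.spectrum)
            if r < thr:
                continue
            shared = set(rows[ei.entry_id]) & set(rows[ej.entry_id])
            if not shared:
                continue
            dts = [
                abs(rows[ei.entry_id][rid] - rows[ej.entry_id][rid]) for rid in shared
            ]
            if max(dts) <= tol:
                report["redundancy"].append(
                    {
                        "entries": [ei.entry_id, ej.entry_id],
                        "spectral_r": r,
                        "max_dtR": max(dts),
                        "n_shared_runs": len(shared),
                    }
                )

    for e in entries:
        others = [o for o in entries if o.entry_id != e.entry_id]
        for i, a in enumerate(others):
            for b in others[i + 1 :]:
                shared = set(rows[a.entry_id]) & set(rows[b.entry_id])
                coelute = [
                    rid
                    for rid in shared
                    if abs(rows[a.entry_id][rid] - rows[b.entry_id][rid]) <= tol
                ]
                if not coelute:
                    continue
                sum_spec = a.spectrum + b.spectrum
                sum_spec = sum_spec / np.linalg.norm(sum_spec)
                if spectral_r(e.spectrum, sum_spec) >= thr:
                    report["sum_spectrum"].append(
                        {
                            "entry": e.entry_id,
                            "summands": [a.entry_id, b.entry_id],
                            "runs_coeluting": coelute,
                        }
                    )

    if column_of_run:
        columns = sorted(set(column_of_run.values()))
        if len(columns) > 1:
            for e in entries:
                assigned_cols = set()
                per_col_runs: dict[str, list[str]] = {c: [] for c in columns}
                for rid in table.run_ids:
                    col = column_of_run.get(rid)
                    if col is None:
                        continue
                    per_col_runs[col].append(rid)
                    if rid in rows[e.entry_id]:
                        assigned_cols.add(col)
                missing = [
                    c for c in columns if per_col_runs[c] and c not in assigned_cols
                ]
                if missing and assigned_cols:
                    report["column_inconsistency"].append(
                        {"entry": e.entry_id, "assigned_columns": sorted(assigned_cols),
                         "unassigned_columns": missing}
                    )
    return report


# ---------------------------------------------------------------------------
# user resolution


def resolve(
    table: AssignmentTable,
    catalog: ComponentCatalog,
    edits: list[dict],
) -> tuple[AssignmentTable, ComponentCatalog]:
    """Apply chromatographer edits and re-validate.

    Edits are dicts: {"action": "delete", "entry": id},
    {"action": "merge", "keep": id, "drop": id},
    {"action": "set_tR", "entry": id, "run_id": rid, "tR": minutes}.
    """
    for edit in edits:
        action = edit.get("action")
        if action == "delete":
            entry = catalog.entry(edit["entry"])  # KeyError if absent
            catalog.pure_set.remove(entry)
            table.entries = [e for e in table.entries if e != entry.entry_id]
            table.cells = {
                k: v for k, v in table.cells.items() if k[0] != entry.entry_id
            }
        elif action == "merge":
            keep = catalog.entry(edit["keep"])
            drop = catalog.entry(edit["drop"])
            keep.members.extend(drop.members)
            mean = np.mean([m.spectrum for m in keep.members], axis=0)
            keep.spectrum = mean / np.linalg.norm(mean)
            # keep's assignments win; fill gaps from drop's
            for rid in table.run_ids:
                ck = table.cells[(keep.entry_id, rid)]
                cd = table.cells.get((drop.entry_id, rid))
                if ck.flag not in (CellFlag.assigned, CellFlag.manual) and cd and cd.flag in (
                    CellFlag.assigned,
                    CellFlag.manual,
                ):
                    table.cells[(keep.entry_id, rid)] = cd
            catalog.pure_set.remove(drop)
            table.entries = [e for e in table.entries if e != drop.entry_id]
            table.cells = {k: v for k, v in table.cells.items() if k[0] != drop.entry_id}
        elif action == "set_tR":
            eid, rid = edit["entry"], edit["run_id"]
            if (eid, rid) not in table.cells:
                raise KeyError(f"no cell ({eid}, {rid})")
            old = table.cells[(eid, rid)]
            table.cells[(eid, rid)] = Cell(float(edit["tR"]), CellFlag.manual, old.best_r)
        else:
            raise ValueError(f"unknown edit action: {action!r}")
    return table, catalog


# ---------------------------------------------------------------------------
# pipeline convenience


def discover(
    runs: list[Chromatogram],
    ms_runs: list[Chromatogram] | None = None,
    thr_uv: float = THR_UV_DEFAULT,
    alert_floor: float = ALERT_FLOOR_DEFAULT,
    rank_cap: int = 6,
    noise_k: float = 3.0,
    valley_ratio: float = 0.5,
    apply_background_filter: bool = True,
) -> tuple[ComponentCatalog, AssignmentTable, dict[str, list[ExtractedComponent]]]:
    """Full discovery pass: segment, resolve, catalog, filter and assign.

    When matching MS runs are supplied, each extracted UV component inherits
    the MS spectrum of the closest-apex MS component in the same run (within
    two peak widths), enabling MS-aware cataloguing.
    """
    extracted_per_run: dict[str, list[ExtractedComponent]] = {}
    clusters_per_run: dict[str, list[PeakCluster]] = {}
    for chrom in runs:
        cls = segment_chromatogram(chrom, noise_k=noise_k, valley_ratio=valley_ratio)
        clusters_per_run[chrom.run_id] = cls
        comps: list[ExtractedComponent] = []
        for k, cl in enumerate(cls):
            _, cc = resolve_cluster(
                cl,
                cluster_id=k,
                cap=rank_cap,
                column_id=chrom.meta.column_id if chrom.meta else "",
                role=chrom.meta.role.value if chrom.meta else "calibration",
            )
            comps.extend(cc)
        extracted_per_run[chrom.run_id] = comps

    ms_mode = ms_runs is not None
    if ms_mode:
        _attach_ms(extracted_per_run, ms_runs, rank_cap)

    all_comps = [c for comps in extracted_per_run.values() for c in comps]
    catalog = build_catalog(all_comps, thr_uv=thr_uv, alert_floor=alert_floor, ms_mode=ms_mode)
    if apply_background_filter:
        catalog = background_filter(catalog, runs, clusters_per_run)
    table = assign(catalog, extracted_per_run)
    return catalog, table, extracted_per_run


def _attach_ms(
    extracted_per_run: dict[str, list[ExtractedComponent]],
    ms_runs: list[Chromatogram],
    rank_cap: int,
    match_tol: float = 0.05,
) -> None:
    """Resolve MS runs and attach MS spectra to UV components whose apex
    lies within ``match_tol`` minutes of an MS component's apex."""
    from .mcr import ms_noise_count

    ms_by_run = {c.run_id: c for c in ms_runs}
    for rid, comps in extracted_per_run.items():
        chrom = ms_by_run.get(rid)
        if chrom is None:
            continue
        ms_comps: list[ExtractedComponent] = []
        for k, cl in enumerate(segment_chromatogram(chrom)):
            _, cc = resolve_cluster(cl, cluster_id=k, cap=rank_cap)
            ms_comps.extend(cc)
        if not ms_comps:
            continue
        axis = chrom.axis.values
        for comp in comps:
            nearest = min(ms_comps, key=lambda m: abs(m.apex_time - comp.apex_time))
            if abs(nearest.apex_time - comp.apex_time) <= match_tol:
                spec = nearest.spectrum
                nz = spec > spec.max() * 1e-4
                ms_dict = {
                    float(axis[j]): 100.0 * spec[j] / spec.max()
                    for j in np.flatnonzero(nz)
                }
                comp.ms_spectrum = ms_dict
                comp.noise_count = ms_noise_count(ms_dict)
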