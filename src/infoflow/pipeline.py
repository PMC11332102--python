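"""Config-driven orchestration of the full causal analysis.

Reproduces the study's table layout on a panel of daily series: per
metropolitan area, three conditional transfer-entropy links with their
grouped-surrogate significance (MLC->NT|MPB, MLC->PT|MPB, MPB->NT|MLC),
partial rank correlations for the significant links, CCM convergence
curves, and the minute-resolution event study.  Runs are deterministic:
per-link seeds are derived from a master seed by stable hashing, and a
manifest records everything needed to re-execute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccm import ccm_convergence, curve_to_rows, select_embedding
from .events import EventStream, count_significant_areas, sweep_windows
from .infocore import symbolize_tertiles
from .partialcorr import lagged_partial_correlation
from .preprocess import (
    DailySeries,
    align_print_media,
    decompose_and_adjust,
    screen_area,
)
from .surrogates import surrogate_test

#: The three hypothesized links: (source, target, conditioner) roles.
LINKS = (
    ("MLC", "NT", "MPB"),
    ("MLC", "PT", "MPB"),
    ("MPB", "NT", "MLC"),
)


@dataclass
class RunConfig:
    periods: tuple[int, ...] = (7, 30, 365)
    min_daily_mean: float = 0.8
    concentration_fraction: float = 1.0 / 3.0
    concentration_window_days: int = 2
    alphabet_size: int = 3
    tie_rule: str = "stable-rank"
    k: int = 1
    B: int = 20000
    alpha: float = 0.05
    seed: int = 0
    ccm_E: int | None = None            # None: select by self-prediction
    ccm_tau: int = 1
    ccm_library_lengths: tuple[int, ...] = (100, 200, 400, 800)
    ccm_replicates: int = 30
    event_semiwidths: tuple[int, ...] = tuple(range(30, 721, 30))
    output_dir: str = "results"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kw = {}
        for key, val in d.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(val, list):
                val = tuple(val)
            kw[key] = val
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(master_seed: int, *labels) -> int:
    """Stable per-task seed below 2**31, from a master seed and labels."""
    tag = ":".join([str(master_seed), *map(str, labels)])
    return zlib.crc32(tag.encode()) % (2**31 - 1)


def _panel_by_area(series_list) -> tuple[DailySeries, dict[str, dict[str, DailySeries]]]:
    mpb = None
    areas: dict[str, dict[str, DailySeries]] = {}
    for s in series_list:
        if s.role == "MPB":
            mpb = s
        else:
            areas.setdefault(s.area, {})[s.role] = s
    if mpb is None:
        raise ValueError("incomplete panel: national MPB series missing")
    for area, roles in areas.items():
        missing = {"MLC", "PT", "NT"} - set(roles)
        if missing:
            raise ValueError(f"incomplete panel: area {area!r} lacks {sorted(missing)}")
    return mpb, areas


def _common_window(series: list[DailySeries]) -> list[DailySeries]:
    start = max(s.dates[0] for s in series)
    end = min(s.dates[-1] for s in series)
    out = []
    for s in series:
        keep = (s.dates >= start) & (s.dates <= end)
        out.append(s.replace(dates=s.dates[keep], values=s.values[keep]))
    return out


def prepare_area(mpb: DailySeries, roles: dict[str, DailySeries], config: RunConfig):
    """Shift print media, adjust, and symbolize one area's four series.

    Returns ``(symbolic, adjusted)`` dicts keyed by role.
    """
    shifted = {
        "MPB": align_print_media(mpb),
        "MLC": align_print_media(roles["MLC"]),
        "PT": roles["PT"],
        "NT": roles["NT"],
    }
    aligned = _common_window(list(shifted.values()))
    adjusted, symbolic = {}, {}
    for s in aligned:
        adj = decompose_and_adjust(s, periods=config.periods)
        adjusted[s.role] = adj
        symbolic[s.role] = symbolize_tertiles(
            adj.residuals, s=config.alphabet_size, tie_rule=config.tie_rule
        )
    return symbolic, adjusted


def run_te_panel(series_list, config: RunConfig):
    """Transfer-entropy and sign analysis over a full panel.

    Returns ``(table1, table2, screening, manifest)``: table1 holds one
    row per area and link with the CTE estimate, 95% surrogate quantile
    and percentile p; table2 the lagged partial rank correlation for
    every significant link; screening the per-area inclusion decisions.
    """
    mpb, areas = _panel_by_area(series_list)
    screen_rows, t1_rows, t2_rows = [], [], []
    for area in sorted(areas):
        decision = screen_area(
            areas[area]["MLC"],
            min_daily_mean=config.min_daily_mean,
            concentration_fraction=config.concentration_fraction,
            concentration_window_days=config.concentration_window_days,
        )
        screen_rows.append(
            {"area": area, "included": decision.included, "reason": decision.reason,
             "mean_per_day": decision.mean_per_day,
             "max_window_fraction": decision.max_window_fraction}
        )
        if not decision.included:
            continue
        symbolic, adjusted = prepare_area(mpb, areas[area], config)
        for src, tgt, cond in LINKS:
            link = f"{src}->{tgt}|{cond}"
            seed = derive_seed(config.seed, area, link)
            res = surrogate_test(
                symbolic[tgt], symbolic[src], [symbolic[cond]],
                k=config.k, B=config.B, alpha=config.alpha, seed=seed,
                source_role=src, target_role=tgt, conditioner_roles=(cond,),
            )
            t1_rows.append(
                {"area": area, "link": link, "te_bits": res.observed,
                 "q95_bits": res.q95, "p_value": res.p_value,
                 "significant": res.significant, "n_transitions": res.n_transitions,
                 "k": config.k, "B": res.B, "seed": seed}
            )
            if res.significant:
                pc = lagged_partial_correlation(
                    adjusted[tgt].residuals, adjusted[src].residuals,
                    adjusted[cond].residuals, lag=1,
                )
                t2_rows.append(
                    {"area": area, "link": link, "rho": pc.rho,
                     "ci_low": pc.ci95[0], "ci_high": pc.ci95[1],
                     "p_value": pc.p_value, "n": pc.n}
                )
    manifest = _manifest(config, stage="te")
    return (
        pd.DataFrame(t1_rows),
        pd.DataFrame(t2_rows),
        pd.DataFrame(screen_rows),
        manifest,
    )


def run_ccm_panel(series_list, config: RunConfig, pairings=(("MPB", "NT"),)):
    """CCM convergence curves for role pairings, per area.

    For pairing ``(A, B)`` the curve labelled ``"x->y"`` is the skill of
    reconstructing A from the embedding of B (evidence A drives B).
    """
    mpb, areas = _panel_by_area(series_list)
    rows = []
    for area in sorted(areas):
        symbolic, adjusted = prepare_area(mpb, areas[area], config)
        for role_x, role_y in pairings:
            x = adjusted[role_x].residuals
            y = adjusted[role_y].residuals
            E = config.ccm_E
            if E is None:
                E = select_embedding(y, E_range=range(1, 7), tau=config.ccm_tau)
            seed = derive_seed(config.seed, area, "ccm", role_x, role_y)
            curves = ccm_convergence(
                x, y, E=E, tau=config.ccm_tau,
                library_lengths=config.ccm_library_lengths,
                replicates=config.ccm_replicates, seed=seed,
            )
            for direction, curve in curves.items():
                for row in curve_to_rows(curve):
                    rows.append({"area": area, "pair": f"{role_x}/{role_y}",
                                 "E": E, **row})
    return pd.DataFrame(rows), _manifest(config, stage="ccm")


def run_event_study(event_data: dict[str, tuple[EventStream, np.ndarray]],
                    config: RunConfig):
    """Sweep the event-response test per area and count significant areas.

    ``event_data`` maps area label to (events, minutely counts).
    """
    results = {}
    rows = []
    for area, (events, counts) in sorted(event_data.items()):
        res = sweep_windows(events, counts, config.event_semiwidths, area=area)
        results[area] = res
        for s, p, n in zip(res.semiwidths, res.p_values, res.n_events):
            rows.append({"area": area, "semiwidth_min": int(s),
                         "p_value": float(p), "n_events": int(n)})
    counts_df = count_significant_areas(results, alpha=config.alpha)
    return pd.DataFrame(rows), counts_df, results, _manifest(config, stage="events")


def _manifest(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
    }


def write_outputs(output_dir, *, table1=None, table2=None, screening=None,
                  ccm_curves=None, event_pvalues=None, event_counts=None,
                  manifest=None) -> None:
    """Serialize run outputs at fixed precision for byte-stable reruns."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    named = {
        "table1.csv": table1, "table2.csv": table2, "screening.csv": screening,
        "ccm_curves.csv": ccm_curves, "event_pvalues.csv": event_pvalues,
        "event_area_counts.csv": event_counts,
    }
    for name, df in named.items():
        if df is not None:
            df.to_csv(out / name, index=False, float_format="%.6g")
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
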