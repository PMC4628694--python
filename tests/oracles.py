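"""Independent brute-force oracles used by the test suite.

Episode detection is re-derived here by scanning a 1-minute grid with the
same sample-and-hold semantics, entirely separate from the interval
algebra in the package.  Boundary times are snapped back to the 0.25 h
lattice used by the random record generator, so comparisons are exact.
"""

import numpy as np

DT = 1.0 / 60.0  # 1-minute grid
LATTICE = 0.25


def _snap(t):
    return round(t / LATTICE) * LATTICE


def _grid(stay):
    n = int(round(stay / DT))
    return np.arange(n + 1) * DT


def held_values(series, grid):
    """Held value at each grid point; NaN before the first sample."""
    idx = np.searchsorted(series.times, grid + 1e-9, side="right") - 1
    out = np.full(len(grid), np.nan)
    ok = idx >= 0
    out[ok] = series.values[idx[ok]]
    return out


def _runs(mask):
    """(start_index, end_index_inclusive) for each maximal True run."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _run_bounds(run, grid, stay):
    i0, i1 = run
    start = _snap(grid[i0])
    end = stay if i1 == len(grid) - 1 else _snap(grid[i1 + 1])
    return start, end


def grid_hold_intervals(series, predicate, stay):
    grid = _grid(stay)
    vals = held_values(series, grid)
    ok = np.zeros(len(grid), dtype=bool)
    finite = ~np.isnan(vals)
    ok[finite] = [predicate(v) for v in vals[finite]]
    return [_run_bounds(r, grid, stay) for r in _runs(ok)]


def _criterion_masks(record, cfg, grid):
    checks = {
        "temperature": ("T", lambda v: v > cfg.temp_high or v < cfg.temp_low),
        "heart_rate": ("HR", lambda v: v > cfg.hr_thresh),
        "respiratory_rate": ("RR", lambda v: v > cfg.rr_thresh),
        "wbc": ("WBC", lambda v: v > cfg.wbc_high or v < cfg.wbc_low),
    }
    masks = {}
    for name, (var, pred) in checks.items():
        s = record.series.get(var)
        if s is None or len(s) == 0:
            continue
        vals = held_values(s, grid)
        m = np.zeros(len(grid), dtype=bool)
        finite = ~np.isnan(vals)
        m[finite] = [pred(v) for v in vals[finite]]
        masks[name] = m
    return masks


def grid_abnormality_episodes(record, cfg):
    """Backtracked, merged, duration-filtered abnormality intervals."""
    stay = record.icu_stay_h
    grid = _grid(stay)
    masks = _criterion_masks(record, cfg, grid)
    if not masks:
        return []
    count = np.sum(list(masks.values()), axis=0)
    met = count >= cfg.min_criteria

    intervals = []
    for i0, i1 in _runs(met):
        back = i0
        for m in masks.values():
            if m[i0]:
                k = i0
                while k > 0 and m[k - 1]:
                    k -= 1
                back = min(back, k)
        start = _snap(grid[back])
        _, end = _run_bounds((i0, i1), grid, stay)
        intervals.append((start, end))

    intervals.sort()
    merged = []
    for a, b in intervals:
        if merged and a - merged[-1][1] < cfg.merge_gap_h:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b - a > cfg.min_episode_h]


def grid_hypotension(record, cfg):
    stay = record.icu_stay_h
    ivs = grid_hold_intervals(record.series["SBP"],
                              lambda v: v < cfg.sbp_thresh, stay)
    return [(a, b) for a, b in ivs if b - a >= cfg.min_hypo_min / 60.0]


def window_fluid(fluids, start, end, cfg):
    lo = start - cfg.fluid_pre_h
    hi = start + (end - start) / 2.0
    return sum(ev.volume for ev in fluids if lo <= ev.time <= hi)


def grid_shock_onset(record, sirs_cfg, shock_cfg):
    """(onset_or_None, reason) recomputed from the grid intervals."""
    abnormal = grid_abnormality_episodes(record, sirs_cfg)
    hypo = grid_hypotension(record, shock_cfg)
    if not abnormal:
        return None, "no_sirs"
    if len(hypo) == 0:
        return None, "no_prolonged_hypotension"
    if len(hypo) == 1:
        return None, "single_hypotension_episode"
    qualified = []
    for a, b in hypo:
        overlaps = any(max(a, x) < min(b, y) for x, y in abnormal)
        if overlaps and window_fluid(record.fluids, a, b,
                                     shock_cfg) > shock_cfg.fluid_thresh_ml:
            qualified.append(a)
    if not qualified:
        return None, "no_fluid_qualified"
    return min(qualified), "labeled"
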