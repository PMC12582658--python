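"""Independent brute-force oracles shared across test modules."""


def day_grid_episodes(days_pills, grace_days=90, mode="pill_count"):
    """Brute-force oracle: walk the calendar one day at a time with a pill
    stockpile, mark covered days, then merge covered runs separated by a
    gap of fewer than ``grace_days`` uncovered days."""
    if not days_pills:
        return []
    supply: dict[int, int] = {}
    for d, p in days_pills:
        supply[d] = supply.get(d, 0) + (90 if mode == "fixed_90" else p)
    covered = []
    stock = 0
    day = min(supply)
    last_day = max(supply)
    while stock > 0 or day <= last_day:
        stock += supply.get(day, 0)
        if stock > 0:
            covered.append(day)
            stock -= 1
        day += 1
    runs = []
    run_start = prev = covered[0]
    for d in covered[1:]:
        if d != prev + 1:
            runs.append((run_start, prev))
            run_start = d
        prev = d
    runs.append((run_start, prev))
    eps = [list(runs[0])]
    for start, end in runs[1:]:
        if start - eps[-1][1] - 1 < grace_days:
            eps[-1][1] = end  # gap bridged: same episode
        else:
            eps.append([start, end])
    return [tuple(e) for e in eps]
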