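"""Independent brute-force re-implementation of the habitat projection.

Written straight from the three printed model conditions and the
relocation rule, with naive loops and its own haversine, so it shares no
code with the package implementation.
"""

import math

EARTH_R = 6371.0


def oracle_classify(t_max_now, t_max_fut, mrr_now, mrr_fut, t_break=32.0):
    if t_max_fut <= t_break and t_max_fut >= t_max_now and mrr_fut <= mrr_now:
        return "stay_c1"
    if t_max_fut <= t_break and (t_max_fut <= t_max_now or mrr_fut <= mrr_now):
        return "stay_c2"
    if t_max_fut > t_break or (t_max_fut >= t_max_now and mrr_fut >= mrr_now):
        return "move_c3"
    raise AssertionError("conditions should be exhaustive")


def oracle_distance(lat1, lon1, lat2, lon2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    a = (
        math.sin((p2 - p1) / 2) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin(math.radians(lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_R * math.asin(math.sqrt(a))


def oracle_project(cells, t_break=32.0):
    """cells: list of dicts with lat, lon, t_max_now, t_max_fut, mrr_now,
    mrr_fut, p.  Returns (final probabilities, overflow, conditions,
    stranded flags) as parallel lists in the input order."""
    n = len(cells)
    conditions = [
        oracle_classify(c["t_max_now"], c["t_max_fut"], c["mrr_now"], c["mrr_fut"], t_break)
        for c in cells
    ]
    out = [0.0] * n
    stranded = [False] * n

    order = sorted(range(n), key=lambda i: (cells[i]["lat"], cells[i]["lon"]))
    for i in order:
        c = cells[i]
        if c["p"] == 0.0:
            continue
        if conditions[i] != "move_c3":
            out[i] += c["p"]
            continue
        # exhaustive nearest-refuge search over every other cell
        best_j, best_key = None, None
        for j in range(n):
            if j == i:
                continue
            d = cells[j]
            if d["mrr_fut"] > c["mrr_now"] or d["t_max_fut"] > t_break:
                continue
            key = (oracle_distance(c["lat"], c["lon"], d["lat"], d["lon"]),
                   d["lat"], d["lon"])
            if best_key is None or key < best_key:
                best_key, best_j = key, j
        if best_j is None:
            stranded[i] = True
        else:
            out[best_j] += c["p"]

    overflow = [max(v - 1.0, 0.0) for v in out]
    capped = [min(v, 1.0) for v in out]
    return capped, overflow, conditions, stranded


def random_scenario(rng, n_side):
    """Randomized n_side x n_side grid of cell dicts on a half-degree grid."""
    cells = []
    for i in range(n_side):
        for j in range(n_side):
            t_now = rng.uniform(18.0, 31.0)
            t_fut = t_now + rng.uniform(-2.0, 4.0)
            mrr_now = 10.0 ** rng.uniform(-9.0, -7.0)
            mrr_fut = mrr_now * rng.uniform(0.5, 2.0)
            p = 0.0 if rng.random() < 0.2 else round(rng.uniform(0.05, 1.0), 3)
            cells.append(
                dict(
                    lat=35.25 + 0.5 * i,
                    lon=-76.25 + 0.5 * j,
                    t_max_now=t_now,
                    t_max_fut=t_fut,
                    mrr_now=mrr_now,
                    mrr_fut=mrr_fut,
                    p=p,
                )
            )
    return cells
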