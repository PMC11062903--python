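"""Independent brute-force oracles shared across test modules."""

from agglearn.chemspace import tanimoto


def brute_force_leader_clustering(records, cutoff):
    """Exhaustive leader clustering: recompute neighbour lists from scratch at
    every step and apply the documented selection rule directly."""
    remaining = {r.id: r for r in records}
    clusters = []
    while remaining:
        counts = {}
        for rid, rec in remaining.items():
            counts[rid] = sum(
                tanimoto(rec.fingerprint, other.fingerprint) >= cutoff
                for other in remaining.values()
            )
        centroid = min(remaining, key=lambda r: (-counts[r], r))
        members = sorted(
            rid
            for rid, rec in remaining.items()
            if tanimoto(remaining[centroid].fingerprint, rec.fingerprint) >= cutoff
        )
        clusters.append((centroid, members))
        for m in members:
            del remaining[m]
    return clusters
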