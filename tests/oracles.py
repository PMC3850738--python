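"""Independent brute-force oracles, deliberately naive.

Each function re-derives a pipeline quantity by direct enumeration or a
textbook formula, sharing no code path with the implementation it
checks.
"""

from __future__ import annotations

import numpy as np


def brute_contacts(structure, partition, cutoff):
    """All intermolecular residue contacts by O(n^2) atom-pair enumeration."""
    rec = [r for r in structure.residues if r.chain_id in partition.receptor_chains]
    lig = [r for r in structure.residues if r.chain_id in partition.ligand_chains]
    pairs = set()
    for rr in rec:
        for lr in lig:
            found = False
            for ra in rr.atoms:
                if ra.element.upper() in ("H", "D"):
                    continue
                for la in lr.atoms:
                    if la.element.upper() in ("H", "D"):
                        continue
                    if np.linalg.norm(ra.position - la.position) <= cutoff:
                        found = True
                        break
                if found:
                    break
            if found:
                pairs.add((rr.key, lr.key))
    return pairs


def svd_kabsch(ref, mov):
    """Classical SVD Kabsch: returns (R, t, rmsd) for R @ mov + t ~ ref."""
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    rc, mc = ref.mean(0), mov.mean(0)
    h = (mov - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = rc - r @ mc
    moved = mov @ r.T + t
    rmsd = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
    return r, t, rmsd


def backbone_coords(structure, chains, atom_names=("N", "CA", "C", "O")):
    out = []
    for res in structure.residues:
        if res.chain_id not in chains:
            continue
        for name in atom_names:
            atom = res.atom(name)
            if atom is not None:
                out.append(atom.position)
    return np.array(out)


def brute_lrmsd(native, decoy, partition):
    """Receptor fit then plain ligand RMSD, recomputed from scratch."""
    nat_rec = backbone_coords(native, partition.receptor_chains)
    dec_rec = backbone_coords(decoy, partition.receptor_chains)
    r, t, _ = svd_kabsch(nat_rec, dec_rec)
    nat_lig = backbone_coords(native, partition.ligand_chains)
    dec_lig = backbone_coords(decoy, partition.ligand_chains) @ r.T + t
    return float(np.sqrt(np.mean(np.sum((dec_lig - nat_lig) ** 2, axis=1))))


def brute_interface_residues(native, partition, cutoff):
    rec = [r for r in native.residues if r.chain_id in partition.receptor_chains]
    lig = [r for r in native.residues if r.chain_id in partition.ligand_chains]
    out = set()
    for rr in rec:
        for lr in lig:
            for ra in rr.atoms:
                if ra.element.upper() in ("H", "D"):
                    continue
                for la in lr.atoms:
                    if la.element.upper() in ("H", "D"):
                        continue
                    if np.linalg.norm(ra.position - la.position) <= cutoff:
                        out.add(rr.key)
                        out.add(lr.key)
    return out


def brute_irmsd(native, decoy, partition, cutoff=10.0):
    """Explicitly re-list interface residues, then SVD Kabsch on them."""
    iface = brute_interface_residues(native, partition, cutoff)
    nat, dec = [], []
    for res in native.residues:
        if res.key not in iface:
            continue
        dres = decoy.residue(res.key)
        for name in ("N", "CA", "C", "O"):
            a, b = res.atom(name), dres.atom(name)
            if a is not None and b is not None:
                nat.append(a.position)
                dec.append(b.position)
    _, _, rmsd = svd_kabsch(np.array(nat), np.array(dec))
    return float(rmsd)


def brute_potential_score(structure, partition, matrix, definition):
    """All receptor-ligand residue pairs, representative rule inline."""
    from dockscore.potentials import AA_INDEX, standard_type

    def rep(res):
        heavy = [a for a in res.atoms if a.element.upper() not in ("H", "D")]
        if definition.representative == "c_beta":
            atom = res.atom("CB") or res.atom("CA")
            return [atom.position]
        if definition.representative == "centroid":
            return [np.mean([a.position for a in heavy], axis=0)]
        return [a.position for a in heavy]

    total = 0.0
    for rr in structure.residues:
        if rr.chain_id not in partition.receptor_chains:
            continue
        tr = standard_type(rr.name)
        if tr is None:
            continue
        for lr in structure.residues:
            if lr.chain_id not in partition.ligand_chains:
                continue
            tl = standard_type(lr.name)
            if tl is None:
                continue
            pts_r, pts_l = rep(rr), rep(lr)
            d = min(np.linalg.norm(np.asarray(p) - np.asarray(q))
                    for p in pts_r for q in pts_l)
            for b, (lo, hi) in enumerate(definition.bins):
                if lo <= d <= hi:
                    total += matrix.entries[AA_INDEX[tr], AA_INDEX[tl], b]
                    break
    return total


def resweep_cluster(order, distance, threshold):
    """Second, independent leader-follower sweep implementation."""
    leaders, assignment = [], {}
    for d in order:
        for leader in leaders:
            if distance(leader, d) <= threshold:
                assignment.setdefault(leader, []).append(d)
                break
        else:
            leaders.append(d)
            assignment[d] = [d]
    return [(leader, assignment[leader]) for leader in leaders]


def naive_complete_linkage(dist, labels):
    """O(n^3) agglomeration; returns the pairwise cophenetic matrix."""
    n = len(labels)
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    active = list(range(n))
    d = {(i, j): dist[i][j] for i in range(n) for j in range(n)}
    next_id = n
    members = dict(clusters)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dd = d[(a, b)]
                if best is None or dd < best[0]:
                    best = (dd, a, b)
        dd, a, b = best
        merged = members[a] + members[b]
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = dd
        members[next_id] = merged
        active = [x for x in active if x not in (a, b)]
        for x in active:
            dm = max(d[(a, x)], d[(b, x)])
            d[(next_id, x)] = dm
            d[(x, next_id)] = dm
        active.append(next_id)
        next_id += 1
    return coph
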