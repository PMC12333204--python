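"""Loop-unrolled reference forward pass for the directed message passing model.

Deliberately naive: explicit Python loops over edges and atoms, neighbor sets
found by scanning the edge list, no batching, no sparse algebra. Serves as an
independent oracle for the vectorized implementation.
"""

import numpy as np

from mflogp.featurization import featurize_molecule


def _relu(x):
    return np.maximum(x, 0.0)


def reference_forward(model, smiles, extra=None):
    """Scaled-space output for one molecule, shape (n_targets,)."""
    cfg = model.config
    w = {k: np.asarray(v, dtype=np.float64) for k, v in model.weights.items()}
    g = featurize_molecule(smiles)
    n_e = g.n_edges

    h0 = [_relu(w["W_in"] @ g.edge_feats[e].astype(np.float64)) for e in range(n_e)]
    h = [v.copy() for v in h0]
    for _ in range(cfg.depth - 1):
        new = []
        for e in range(n_e):
            v = g.src[e]
            msg = np.zeros(cfg.hidden_size)
            for k in range(n_e):
                # edges arriving at v, excluding the reverse of e
                if g.tgt[k] == v and k != g.rev[e]:
                    msg = msg + h[k]
            new.append(_relu(h0[e] + w["W_m"] @ msg))
        h = new

    atom_vecs = []
    for a in range(g.n_atoms):
        s = np.zeros(cfg.hidden_size)
        for k in range(n_e):
            if g.tgt[k] == a:
                s = s + h[k]
        x = np.concatenate([g.atom_feats[a].astype(np.float64), s])
        atom_vecs.append(_relu(w["W_a"] @ x + w["b_a"]))
    mol = np.sum(atom_vecs, axis=0)
    if cfg.aggregation == "mean":
        mol = mol / g.n_atoms

    z = mol
    if cfg.extra_feature_dim:
        z = np.concatenate([z, np.asarray(extra, dtype=np.float64).ravel()])
    for li in range(cfg.ffn_layers):
        z = w[f"ffn_W{li}"] @ z + w[f"ffn_b{li}"]
        if li < cfg.ffn_layers - 1:
            z = _relu(z)
    return z
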