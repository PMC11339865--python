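"""The pKa network: directed-bond message passing with retention blocks.

Composition, per molecule:

1. every directed bond v->w gets an initial hidden state
   h0 = ReLU(W_init . [x_v ; e_vw]);
2. for T iterations, each bond collects messages from incoming bonds
   (excluding its own reverse), the candidate messages pass through a
   graph-mode bond retention block whose decay follows the topological
   distance between the bonds' source atoms, and states update residually:
   h <- ReLU(h0 + W_m . RetentionBlock(m)) with dropout;
3. incoming bond states are summed per atom, concatenated with the atom
   features, projected, and refined by a multi-head atom retention block
   biased by the scaled adjacency / distance / Coulomb matrices;
4. atom states are sum-aggregated to a molecule vector (permutation
   invariant), fused with five standardized quantum-mechanical scalars
   (enthalpy, free energy, HOMO, LUMO, HOMO-LUMO gap), and a small
   fully-connected head emits the pKa estimate.

Ablation toggles swap retention for softmax attention, drop the QM fusion,
or drop the structural bias matrices, without changing any shape contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import chem_graph
from .autodiff import Tensor, concatenate, relu
from .chem_graph import InterAtomicMatrices, Molecule
from .retention import (RetentionParams, biased_multihead_attention,
                        biased_multihead_retention)

QM_FEATURE_NAMES = ("enthalpy", "free_energy", "homo", "lumo", "gap")


@dataclass
class ModelConfig:
    hidden_size: int = 300
    depth: int = 3                 # message-passing iterations T
    n_heads: int = 6
    dropout: float = 0.1
    ffn_layers: int = 2
    qm_dim: int = 5
    use_qm: bool = True
    use_retention: bool = True     # False -> softmax attention (ablation)
    use_bias_matrices: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.depth < 1:
            raise ValueError("message-passing depth T must be >= 1")
        if self.use_qm and self.qm_dim != 5:
            raise ValueError("qm_dim must be 5 when use_qm is enabled")
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class MoleculeTensors:
    """Featurized molecule cached for repeated forward passes."""

    smiles: str
    atom_feats: np.ndarray          # (n_atoms, ATOM_FEATURE_DIM)
    bond_feats: np.ndarray          # (2m, BOND_FEATURE_DIM)
    src: np.ndarray                 # (2m,) source atom of each directed bond
    dst: np.ndarray                 # (2m,)
    mats: InterAtomicMatrices
    init_feats: np.ndarray          # (2m, fa+fb) [x_src ; e]
    msg_mask: np.ndarray            # (2m, 2m): msg_mask[e,f]=1 iff f feeds e
    incoming: np.ndarray            # (n_atoms, 2m): incoming[v,f]=1 iff dst[f]=v
    bond_dtop: np.ndarray           # (2m, 2m) Dtop between source atoms

    @property
    def n_atoms(self) -> int:
        return self.atom_feats.shape[0]


def featurize_molecule(mol: Molecule | str) -> MoleculeTensors:
    if isinstance(mol, str):
        mol = chem_graph.parse_molecule(mol)
    if mol.n_atoms == 0:
        raise ValueError("cannot featurize an empty molecule")
    atom_feats = chem_graph.atom_featurize(mol)
    bond_feats = chem_graph.bond_featurize(mol)
    mats = chem_graph.interatomic_matrices(mol)
    db = chem_graph.directed_bonds(mol)
    nb = len(db)
    src = np.array([i for i, _ in db], dtype=int).reshape(nb)
    dst = np.array([j for _, j in db], dtype=int).reshape(nb)
    init_feats = (np.concatenate([atom_feats[src], bond_feats], axis=1)
                  if nb else np.zeros((0, atom_feats.shape[1] + bond_feats.shape[1])))
    # directed bond e = (v -> w) receives h_{k -> v} for k in N(v) \ {w}:
    # feeder f must end at src[e] and must not be the reverse of e.
    rev = np.arange(nb) ^ 1 if nb else np.zeros(0, dtype=int)
    msg_mask = np.zeros((nb, nb))
    for e in range(nb):
        for f in range(nb):
            if dst[f] == src[e] and f != rev[e]:
                msg_mask[e, f] = 1.0
    incoming = np.zeros((mol.n_atoms, nb))
    for f in range(nb):
        incoming[dst[f], f] = 1.0
    bond_dtop = mats.Dtop[np.ix_(src, src)] if nb else np.zeros((0, 0))
    return MoleculeTensors(smiles=mol.smiles, atom_feats=atom_feats,
                           bond_feats=bond_feats, src=src, dst=dst, mats=mats,
                           init_feats=init_feats, msg_mask=msg_mask,
                           incoming=incoming, bond_dtop=bond_dtop)


class PkaModel:
    """Retention-MPNN pKa regressor with explicit NumPy parameters."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = int(seed)
        self.qm_mean = np.zeros(self.config.qm_dim)
        self.qm_std = np.ones(self.config.qm_dim)
        self.params: dict[str, Tensor] = {}
        self._build(np.random.default_rng(self.seed))

    # ----------------------------------------------------------------- build
    def _w(self, name: str, rows: int, cols: int, rng) -> Tensor:
        t = Tensor(rng.normal(0.0, 1.0 / np.sqrt(rows), size=(rows, cols)),
                   requires_grad=True)
        self.params[name] = t
        return t

    def _b(self, name: str, cols: int) -> Tensor:
        t = Tensor(np.zeros(cols), requires_grad=True)
        self.params[name] = t
        return t

    def _retention_params(self, prefix: str, rng, use_bias: bool) -> RetentionParams:
        h = self.config.hidden_size
        p = RetentionParams.create(h, self.config.n_heads, rng,
                                   use_bias=use_bias, trainable=True)
        for nm, w in zip(("Wq", "Wk", "Wv", "Wo"), p.weights()):
            self.params[f"{prefix}_{nm}"] = w
        return p

    def _build(self, rng) -> None:
        cfg = self.config
        fa, fb, h = chem_graph.ATOM_FEATURE_DIM, chem_graph.BOND_FEATURE_DIM, cfg.hidden_size
        self._w("W_init", fa + fb, h, rng); self._b("b_init", h)
        self._w("W_m", h, h, rng); self._b("b_m", h)
        self.bond_ret = self._retention_params("bond", rng, use_bias=False)
        self._w("W_a", fa + h, h, rng); self._b("b_a", h)
        self.atom_ret = self._retention_params("atom", rng,
                                               use_bias=cfg.use_bias_matrices)
        d_in = h + (cfg.qm_dim if cfg.use_qm else 0)
        for k in range(cfg.ffn_layers):
            self._w(f"W_f{k}", d_in, h, rng); self._b(f"b_f{k}", h)
            d_in = h
        self._w("W_out", d_in, 1, rng); self._b("b_out", 1)

    # --------------------------------------------------------------- helpers
    def _dropout(self, x, rng):
        p = self.config.dropout
        if rng is None or p == 0.0:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * mask

    def _block(self, X, mats, params, dtop, use_bias):
        fn = (biased_multihead_retention if self.config.use_retention
              else biased_multihead_attention)
        return fn(X, mats, params, dtop, use_bias_mats=use_bias)

    # ------------------------------------------------------------ spec stages
    def init_bond_states(self, mt: MoleculeTensors):
        """h0_{v->w} = ReLU(W_init . [x_v ; e_vw]) for every directed bond."""
        return relu(Tensor(mt.init_feats) @ self.params["W_init"]
                    + self.params["b_init"])

    def bond_message_pass(self, h0, mt: MoleculeTensors, rng=None):
        """T iterations of neighbor-summed messages through the bond
        retention block with a residual to the initial states."""
        if mt.init_feats.shape[0] == 0:
            return h0
        H = h0
        for _ in range(self.config.depth):
            msgs = Tensor(mt.msg_mask) @ H
            ret = self._block(msgs, None, self.bond_ret, mt.bond_dtop,
                              use_bias=False)
            H = relu(h0 + ret @ self.params["W_m"] + self.params["b_m"])
            H = self._dropout(H, rng)
        return H

    def atom_readin(self, bond_states, mt: MoleculeTensors):
        """Sum incoming bond states per atom, concat atom features, project,
        refine with the biased multi-head atom retention block."""
        if mt.init_feats.shape[0] == 0:
            summed = Tensor(np.zeros((mt.n_atoms, self.config.hidden_size)))
        else:
            summed = Tensor(mt.incoming) @ bond_states
        z = (concatenate([Tensor(mt.atom_feats), summed], axis=1)
             @ self.params["W_a"] + self.params["b_a"])
        return self._block(z, mt.mats, self.atom_ret, mt.mats.Dtop,
                           use_bias=self.config.use_bias_matrices)

    def molecule_readout(self, atom_states):
        """Permutation-invariant sum aggregation over atoms."""
        if atom_states.shape[0] == 0:
            raise ValueError("cannot aggregate an empty molecule")
        return atom_states.sum(axis=0, keepdims=True)

    def fuse_qm_and_predict(self, mol_vec, qm: np.ndarray | None, rng=None):
        """Concatenate standardized QM scalars and run the FFN head."""
        cfg = self.config
        if cfg.use_qm:
            if qm is None or np.asarray(qm).shape != (cfg.qm_dim,):
                raise ValueError(f"model requires {cfg.qm_dim} QM scalars")
            qz = (np.asarray(qm, dtype=float) - self.qm_mean) / self.qm_std
            x = concatenate([mol_vec, Tensor(qz.reshape(1, -1))], axis=1)
        else:
            x = mol_vec
        for k in range(cfg.ffn_layers):
            x = relu(x @ self.params[f"W_f{k}"] + self.params[f"b_f{k}"])
            x = self._dropout(x, rng)
        return x @ self.params["W_out"] + self.params["b_out"]

    # ---------------------------------------------------------------- public
    def forward(self, mt: MoleculeTensors, qm: np.ndarray | None = None,
                rng: np.random.Generator | None = None) -> Tensor:
        """Full forward pass; pass ``rng`` to enable dropout (training)."""
        h0 = self.init_bond_states(mt)
        H = self.bond_message_pass(h0, mt, rng)
        atom_states = self.atom_readin(H, mt)
        mol_vec = self.molecule_readout(atom_states)
        return self.fuse_qm_and_predict(mol_vec, qm, rng)

    def predict(self, smiles: str, qm: np.ndarray | None = None) -> float:
        """Deterministic inference (dropout off) for one molecule."""
        return self.forward(featurize_molecule(smiles), qm).data.item()

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    # ------------------------------------------------------------ checkpoint
    SCHEMA_VERSION = 1

    def save(self, path: str) -> None:
        meta = {"config": asdict(self.config), "seed": self.seed,
                "schema_version": self.SCHEMA_VERSION}
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            qm_mean=self.qm_mean, qm_std=self.qm_std, **arrays)

    @classmethod
    def load(cls, path: str) -> "PkaModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]), seed=meta["seed"])
            model.qm_mean = data["qm_mean"]
            model.qm_std = data["qm_std"]
            for k, t in model.params.items():
                t.data = data[f"param::{k}"].copy()
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()


def predict_pka(smiles: str, qm: np.ndarray | None, checkpoint: str) -> float:
    """End-to-end prediction from a SMILES string and a saved checkpoint."""
    return PkaModel.load(checkpoint).predict(smiles, qm)
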