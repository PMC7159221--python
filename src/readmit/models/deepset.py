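"""Medical-code-embedding deep set model (ME-DS).

Each admission is scored from
``[principal-dx embedding, rho(sum_c phi(e_c)) over secondary dx,
rho_p(sum_c phi_p(e_c)) over procedures, hospital embedding e_h, age, sex]``
followed by a dense head and a two-unit softmax. Sum pooling over the
unordered code sets makes the model exactly permutation invariant and
lets set cardinality (itself predictive of readmission) survive pooling;
empty sets pool to the zero vector. The GloVe code embeddings are frozen
by default (``finetune_embeddings=True`` unfreezes them). The hospital
ID enters as a learned 1-dimensional embedding, the network analogue of
the hierarchical model's random intercept.

Because phi acts on a code's (frozen) embedding only, phi is evaluated
once per vocabulary entry per batch and pooled through the sparse
record-code incidence matrix — never per code occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ..embedding import EmbeddingTable
from .base import HospitalAssignment, InputError, RiskModel, _check_probabilities
from .nn import Adam, Dropout, he_init, relu, softmax, softmax_xent

__all__ = ["SetEncodedCohort", "DeepSetModel", "encode_cohort", "fit_deepset"]


@dataclass
class SetEncodedCohort:
    """Index-encoded records for the deep set model.

    ``principal_idx`` indexes the dx vocabulary (-1 when out of
    vocabulary, which maps to a zero embedding); ``M_sec``/``M_proc`` are
    binary record x vocabulary incidence matrices over secondary
    diagnoses and procedures.
    """

    principal_idx: np.ndarray
    M_sec: sparse.csr_matrix
    M_proc: sparse.csr_matrix
    age_z: np.ndarray
    female: np.ndarray
    hospital_ids: np.ndarray

    def __len__(self) -> int:
        return self.principal_idx.shape[0]

    def take(self, idx: np.ndarray) -> "SetEncodedCohort":
        return SetEncodedCohort(self.principal_idx[idx], self.M_sec[idx],
                                self.M_proc[idx], self.age_z[idx],
                                self.female[idx], self.hospital_ids[idx])


def encode_cohort(records, dx_table: EmbeddingTable, proc_table: EmbeddingTable,
                  age_mean: float, age_sd: float) -> SetEncodedCohort:
    """Encode records against the fitted embedding vocabularies."""
    dx_index = {c: i for i, c in enumerate(dx_table.codes)}
    proc_index = {c: i for i, c in enumerate(proc_table.codes)}
    n = len(records)
    prin = np.array([dx_index.get(c, -1) for c in records["principal_dx"]],
                    dtype=np.int64)

    def _inc(lists, index, width):
        rows, cols = [], []
        for i, lst in enumerate(lists):
            seen = {index[c] for c in lst if c in index}
            rows.extend([i] * len(seen))
            cols.extend(seen)
        return sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, width))

    M_sec = _inc(records["secondary_dx"], dx_index, len(dx_table.codes))
    M_proc = _inc(records["procedures"], proc_index, len(proc_table.codes))
    age_z = (records["age"].to_numpy(dtype=float) - age_mean) / age_sd
    return SetEncodedCohort(prin, M_sec, M_proc, age_z,
                            records["female"].to_numpy(dtype=float),
                            records["hospital_id"].to_numpy())


class DeepSetModel(RiskModel):
    model_kind = "ME-DS"
    has_hospital_effect = True

    def __init__(self, E_dx, E_proc, params, hospital_index, history):
        self.E_dx = E_dx          # (V_dx, d_dx) embeddings (plus zero OOV row)
        self.E_proc = E_proc
        self.params = params      # phi/rho/head weights and hospital embeddings
        self.hospital_index = dict(hospital_index)
        self.history = history
        self.d_dx = E_dx.shape[1]

    def hospital_ids(self):
        return list(self.hospital_index)

    # --- forward pieces -------------------------------------------------
    def _representation(self, data: SetEncodedCohort) -> np.ndarray:
        """Everything before the head, except the hospital-embedding column."""
        P = self.params
        F = relu(self.E_dx @ P["Wphi"] + P["bphi"])
        pool = data.M_sec @ F
        r_sec = relu(pool @ P["Wr"] + P["br"])
        Fp = relu(self.E_proc @ P["Wphip"] + P["bphip"])
        poolp = data.M_proc @ Fp
        r_proc = relu(poolp @ P["Wrp"] + P["brp"])
        prin = np.vstack([self.E_dx, np.zeros((1, self.d_dx))])[data.principal_idx]
        return np.hstack([prin, r_sec, r_proc,
                          data.age_z[:, None], data.female[:, None]])

    def _hospital_effect(self, data: SetEncodedCohort, assignment):
        e = self.params["e"]
        if assignment == HospitalAssignment.ACTUAL:
            mean_e = float(e.mean())
            return np.array([e[self.hospital_index[h]]
                             if h in self.hospital_index else mean_e
                             for h in data.hospital_ids])
        if assignment == HospitalAssignment.POPULATION:
            return np.full(len(data), float(e.mean()))
        kind, h = assignment
        if kind != "forced":
            raise InputError(f"unknown hospital assignment {assignment!r}")
        if h not in self.hospital_index:
            raise InputError(f"unknown forced hospital {h!r}")
        return np.full(len(data), float(e[self.hospital_index[h]]))

    def _head(self, rep: np.ndarray, eh: np.ndarray) -> np.ndarray:
        P = self.params
        # hospital-embedding column sits between rep and the head weights:
        # W1 rows are laid out as [rep features..., e_h]
        a = rep @ P["W1"][:-1] + eh[:, None] * P["W1"][-1] + P["b1"]
        h = relu(a)
        return softmax(h @ P["W2"] + P["b2"])

    def predict(self, inputs: SetEncodedCohort,
                assignment=HospitalAssignment.ACTUAL) -> np.ndarray:
        rep = self._representation(inputs)
        eh = self._hospital_effect(inputs, assignment)
        return _check_probabilities(self._head(rep, eh)[:, 1])

    def predictive_margins(self, inputs: SetEncodedCohort):
        """Mean forced-hospital prediction over all records, per hospital.

        Equivalent to looping ``predict(inputs, forced(h))`` over
        hospitals, but reuses the shared record representation.
        """
        P = self.params
        rep = self._representation(inputs)
        base = rep @ P["W1"][:-1] + P["b1"]
        w_e = P["W1"][-1]
        ids = list(self.hospital_index)
        means = np.empty(len(ids))
        for j, h in enumerate(ids):
            a = relu(base + P["e"][self.hospital_index[h]] * w_e)
            p = softmax(a @ P["W2"] + P["b2"])[:, 1]
            means[j] = p.mean()
        return np.array(ids), means


def fit_deepset(train: SetEncodedCohort, y_train, val: SetEncodedCohort, y_val,
                dx_table: EmbeddingTable, proc_table: EmbeddingTable,
                phi_width: int = 64, rho_width: int = 64, head_width: int = 64,
                dropout: float = 0.3, learning_rate: float = 0.0002,
                batch_size: int = 256, max_epochs: int = 50, patience: int = 5,
                finetune_embeddings: bool = False, seed: int = 0) -> DeepSetModel:
    """Train the ME-DS model (Adam, categorical cross-entropy, early
    stopping on validation loss); GloVe embeddings frozen by default."""
    if train.M_sec.shape[1] != len(dx_table.codes):
        raise InputError("diagnosis embedding dimension mismatch with encoding")
    if train.M_proc.shape[1] != len(proc_table.codes):
        raise InputError("procedure embedding dimension mismatch with encoding")
    rng = np.random.default_rng(seed)
    E_dx = dx_table.vectors.astype(np.float64).copy()
    E_proc = proc_table.vectors.astype(np.float64).copy()
    d_dx, d_proc = E_dx.shape[1], E_proc.shape[1]

    hospitals = np.unique(train.hospital_ids)
    hindex = {h: i for i, h in enumerate(hospitals)}
    rep_dim = d_dx + rho_width + rho_width + 2  # prin, r_sec, r_proc, age, sex
    params = {
        "Wphi": he_init(rng, d_dx, phi_width), "bphi": np.zeros(phi_width),
        "Wphip": he_init(rng, d_proc, phi_width), "bphip": np.zeros(phi_width),
        "Wr": he_init(rng, phi_width, rho_width), "br": np.zeros(rho_width),
        "Wrp": he_init(rng, phi_width, rho_width), "brp": np.zeros(rho_width),
        "W1": he_init(rng, rep_dim + 1, head_width), "b1": np.zeros(head_width),
        "W2": he_init(rng, head_width, 2), "b2": np.zeros(2),
        "e": rng.normal(0.0, 0.01, hospitals.size),
    }
    opt = Adam(params, learning_rate)
    drop = Dropout(dropout, rng)
    y_train = np.asarray(y_train).astype(np.int64)
    y_val = np.asarray(y_val).astype(np.int64)
    model = DeepSetModel(E_dx, E_proc, params, hindex, history=[])

    train_h = np.array([hindex[h] for h in train.hospital_ids])

    def val_loss() -> float:
        rep = model._representation(val)
        eh = model._hospital_effect(val, HospitalAssignment.ACTUAL)
        a = rep @ params["W1"][:-1] + eh[:, None] * params["W1"][-1] + params["b1"]
        logits = relu(a) @ params["W2"] + params["b2"]
        loss, _ = softmax_xent(logits, y_val)
        return loss

    best_loss = val_loss()
    best = {k: v.copy() for k, v in params.items()}
    best_E = (E_dx.copy(), E_proc.copy()) if finetune_embeddings else None
    history = [best_loss]
    bad = 0
    n = len(train)
    for _ in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            b = train.take(idx)
            yb = y_train[idx]
            hb = train_h[idx]

            # forward
            Aphi = E_dx @ params["Wphi"] + params["bphi"]
            F = relu(Aphi)
            pool = b.M_sec @ F
            Ar = pool @ params["Wr"] + params["br"]
            r_sec = relu(Ar)
            Aphip = E_proc @ params["Wphip"] + params["bphip"]
            Fp = relu(Aphip)
            poolp = b.M_proc @ Fp
            Arp = poolp @ params["Wrp"] + params["brp"]
            r_proc = relu(Arp)
            prin = np.vstack([E_dx, np.zeros((1, d_dx))])[b.principal_idx]
            rep = np.hstack([prin, r_sec, r_proc,
                             b.age_z[:, None], b.female[:, None]])
            eh = params["e"][hb]
            a1 = rep @ params["W1"][:-1] + eh[:, None] * params["W1"][-1] + params["b1"]
            h1 = relu(a1)
            h1d = drop.forward(h1, train=True)
            logits = h1d @ params["W2"] + params["b2"]
            _, gl = softmax_xent(logits, yb)

            # backward
            gW2 = h1d.T @ gl
            gb2 = gl.sum(axis=0)
            gh1 = drop.backward(gl @ params["W2"].T) * (a1 > 0)
            gW1 = np.vstack([rep.T @ gh1, (eh[None, :] @ gh1)])
            gb1 = gh1.sum(axis=0)
            grep = gh1 @ params["W1"][:-1].T
            geh = gh1 @ params["W1"][-1]
            ge = np.zeros_like(params["e"])
            np.add.at(ge, hb, geh)

            gprin = grep[:, :d_dx]
            gr_sec = grep[:, d_dx:d_dx + r_sec.shape[1]]
            gr_proc = grep[:, d_dx + r_sec.shape[1]:d_dx + 2 * r_sec.shape[1]]

            gAr = gr_sec * (Ar > 0)
            gWr = pool.T @ gAr
            gbr = gAr.sum(axis=0)
            gpool = gAr @ params["Wr"].T
            gF = np.asarray(b.M_sec.T @ gpool)
            gWphi = E_dx.T @ (gF * (Aphi > 0))
            gbphi = (gF * (Aphi > 0)).sum(axis=0)

            gArp = gr_proc * (Arp > 0)
            gWrp = poolp.T @ gArp
            gbrp = gArp.sum(axis=0)
            gpoolp = gArp @ params["Wrp"].T
            gFp = np.asarray(b.M_proc.T @ gpoolp)
            gWphip = E_proc.T @ (gFp * (Aphip > 0))
            gbphip = (gFp * (Aphip > 0)).sum(axis=0)

            grads = {"Wphi": gWphi, "bphi": gbphi,
                     "Wphip": gWphip, "bphip": gbphip,
                     "Wr": gWr, "br": gbr, "Wrp": gWrp, "brp": gbrp,
                     "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "e": ge}
            opt.step(grads)

            if finetune_embeddings:
                gE = (gF * (Aphi > 0)) @ params["Wphi"].T
                np.add.at(gE, b.principal_idx[b.principal_idx >= 0],
                          gprin[b.principal_idx >= 0])
                E_dx -= learning_rate * gE
                E_proc -= learning_rate * ((gFp * (Aphip > 0)) @ params["Wphip"].T)

        vl = val_loss()
        history.append(vl)
        if not np.isfinite(vl):
            raise RuntimeError("ME-DS training diverged (non-finite loss)")
        if vl < best_loss - 1e-6:
            best_loss = vl
            best = {k: v.copy() for k, v in params.items()}
            if finetune_embeddings:
                best_E = (E_dx.copy(), E_proc.copy())
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    if finetune_embeddings and best_E is not None:
        E_dx, E_proc = best_E
    model.E_dx, model.E_proc = E_dx, E_proc
    model.params = best
    model.history = history
    return model
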