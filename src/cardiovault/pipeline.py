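"""End-to-end secured prediction pipeline and the authentication stub.

Stages, in order: (1) cohort generation or loading; (2) key generation
(timed); (3) per-record encryption (timed); (4) ledger commit with Merkle
roots; (5) audit and hash-chained log check; (6) decryption (timed) with a
byte-equality assertion against the originals; (7) classifier training —
baseline or AOA-tuned — on the decrypted training split; (8) prediction on
the held-out split; (9) evaluation metrics; (10) alert objects for
predicted-abnormal patients.  Any integrity failure aborts with the stage
name.

All randomness flows from a single root seed split per stage; ledger
timestamps use a deterministic logical clock, and wall-clock timings are
quarantined in the report's ``hardware_dependent`` section, so a run is
bitwise reproducible (outside that section) under a fixed seed.

Authentication is a salted-hash credential store standing in for the
distributed key-issuing narrative of the original design: registration,
login (failure messages indistinguishable between unknown user and wrong
password), and session verification that routes back to registration when
expired.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from . import cipher, ledger, metrics
from .cohort import (CohortSpec, PatientRecord, FEATURE_NAMES, generate_cohort,
                     feature_matrix, impute_missing, read_cleveland, split)
from .net import NetworkConfig, train, predict
from .tuning import SearchSpace, FitnessSpec, search
from .aoa import AOAConfig

__all__ = [
    "CredentialStore",
    "Session",
    "PipelineConfig",
    "PipelineIntegrityError",
    "AlertMessage",
    "RunReport",
    "run_pipeline",
    "serialize_record",
    "parse_record",
]


# --------------------------------------------------------------------------
# authentication stub

@dataclass
class Session:
    username: str
    token: str
    expires_at: float


class CredentialStore:
    """Local salted-hash credential store (roles: patient, hospital, admin).

    Salts come from a seeded stream so a pipeline run is reproducible;
    passwords are never stored in clear.
    """

    def __init__(self, seed: int = 0, session_ttl: float = 3600.0):
        self._users: Dict[str, Tuple[bytes, bytes, str]] = {}
        self._rng = np.random.default_rng(seed)
        self._ttl = session_ttl

    def _hash(self, salt: bytes, password: str) -> bytes:
        return hashlib.sha256(salt + password.encode("utf-8")).digest()

    def register(self, username: str, password: str, role: str = "patient") -> None:
        if username in self._users:
            raise ValueError(f"user {username!r} already registered")
        if role not in ("patient", "hospital", "admin"):
            raise ValueError(f"unknown role {role!r}")
        salt = self._rng.bytes(16)
        self._users[username] = (salt, self._hash(salt, password), role)

    def login(self, username: str, password: str) -> Optional[Session]:
        """A session on success, None otherwise; unknown users and wrong
        passwords are indistinguishable to the caller."""
        entry = self._users.get(username)
        if entry is None:
            return None
        salt, digest, _ = entry
        if self._hash(salt, password) != digest:
            return None
        token = self._rng.bytes(16).hex()
        return Session(username=username, token=token,
                       expires_at=time.monotonic() + self._ttl)

    def verify(self, session: Optional[Session]) -> bool:
        """True iff the session is live; False routes the caller back to
        registration."""
        return (session is not None
                and session.username in self._users
                and time.monotonic() < session.expires_at)

    def salt_of(self, username: str) -> bytes:
        """Exposed for tests (salt-uniqueness property)."""
        return self._users[username][0]


# --------------------------------------------------------------------------
# record <-> bytes codec (canonical, so byte equality is meaningful)

def serialize_record(record: PatientRecord) -> bytes:
    fields = [record.patient_id, str(record.label)]
    fields += [repr(float(record.features[f])) for f in FEATURE_NAMES]
    return "|".join(fields).encode("utf-8")


def parse_record(data: bytes) -> PatientRecord:
    parts = data.decode("utf-8").split("|")
    if len(parts) != 2 + len(FEATURE_NAMES):
        raise ValueError("malformed serialized record")
    feats = {f: float(v) for f, v in zip(FEATURE_NAMES, parts[2:])}
    return PatientRecord(patient_id=parts[0], features=feats,
                         label=int(parts[1]))


# --------------------------------------------------------------------------
# pipeline

class PipelineIntegrityError(RuntimeError):
    """Raised when a stage's integrity check fails; names the stage."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"integrity failure at stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class AlertMessage:
    """Stand-in for the mobile alert: emitted only for predicted-abnormal."""

    patient_id: str
    predicted_class: int
    probability: float
    timestamp: int
    delivery_target: str = "hm-alert-queue"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortSpec | None = None            # generated when set
    cleveland_path: str | None = None           # ...or loaded from CSV
    test_fraction: float = 0.25
    key_bits: int = 64
    block_size_k: int = 2
    cipher_chaining: bool = False
    records_per_block: int = 16
    tune: bool = False
    net_config: NetworkConfig | None = None     # default: baseline setting
    search_space: SearchSpace | None = None
    aoa_config: AOAConfig | None = None         # default small search budget
    n_folds: int = 3


@dataclass
class RunReport:
    stages: List[str] = field(default_factory=list)
    cohort_summary: dict = field(default_factory=dict)
    key_info: dict = field(default_factory=dict)
    ledger_jsonl: str = ""
    audit: dict = field(default_factory=dict)
    decryption_ok: bool = False
    hyperparameters: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    alerts: List[dict] = field(default_factory=list)
    hardware_dependent: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def comparable(self) -> dict:
        """Everything except the wall-clock section (for reproducibility
        checks)."""
        d = asdict(self)
        d.pop("hardware_dependent")
        return d


def _stage_seeds(root_seed: int, n: int = 8) -> List[int]:
    ss = np.random.SeedSequence(root_seed)
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def run_pipeline(
    config: PipelineConfig,
    tamper: Callable[[Dict[str, bytes], List[ledger.Block]], None] | None = None,
) -> RunReport:
    """Run all ten stages; see the module docstring.

    ``tamper``, used by tests, mutates the ciphertext storage and/or chain
    between the ledger commit and the audit; a non-trivial tamper makes the
    audit stage abort.
    """
    report = RunReport()
    seeds = _stage_seeds(config.seed)
    logical_clock = iter(range(10**9))  # deterministic ledger timestamps

    # stage 1: cohort
    if config.cohort is not None:
        spec = replace(config.cohort, seed=seeds[0])
        records = generate_cohort(spec)
        impute_missing(records)
    elif config.cleveland_path is not None:
        records, _ = read_cleveland(config.cleveland_path)
    else:
        raise ValueError("config needs a cohort spec or a Cleveland path")
    if len(records) < 8:
        raise ValueError("cohort too small for a meaningful run")
    train_recs, test_recs = split(records, config.test_fraction, seed=seeds[1])
    report.cohort_summary = {
        "n": len(records),
        "n_train": len(train_recs),
        "n_test": len(test_recs),
        "prevalence": float(np.mean([r.label for r in records])),
    }
    report.stages.append("cohort")

    # stage 2: key generation (timed)
    (pub, priv), t_key = metrics.time_phase(
        "key_generation",
        lambda: cipher.generate_keypair(config.key_bits, config.block_size_k,
                                        seed=seeds[2]),
    )
    report.key_info = {"bits": pub.n.bit_length(), "k": pub.k, "e": pub.e,
                       "chaining": config.cipher_chaining}
    report.stages.append("keygen")

    # stage 3: per-record encryption (timed)
    plaintexts = {r.patient_id: serialize_record(r) for r in records}

    def _encrypt_all() -> Dict[str, bytes]:
        store: Dict[str, bytes] = {}
        for rid, data in plaintexts.items():
            blocks = cipher.encrypt_record(data, pub, chain=config.cipher_chaining)
            store[rid] = json.dumps([[str(v) for v in b] for b in blocks]).encode()
        return store

    storage, t_enc = metrics.time_phase("encryption", _encrypt_all)
    report.stages.append("encrypt")

    # stage 4: ledger commit
    chain: List[ledger.Block] = []
    nonce_rng = np.random.default_rng(seeds[3])
    ids = list(plaintexts)
    for start in range(0, len(ids), config.records_per_block):
        batch = [(rid, storage[rid]) for rid in ids[start:start + config.records_per_block]]
        ledger.append_block(chain, batch, clock=lambda: next(logical_clock),
                            nonce_rng=nonce_rng)
    report.ledger_jsonl = ledger.chain_to_jsonl(chain)
    report.stages.append("ledger")

    if tamper is not None:
        tamper(storage, chain)

    # stage 5: audit + log check
    chain_report = ledger.verify_chain(chain)
    audit_report = ledger.audit(chain, storage)
    log = ledger.AuditLog()
    ledger.generate_log(audit_report, log, timestamp=next(logical_clock))
    log_ok = ledger.check_log(log)
    report.audit = {
        "chain_valid": chain_report.valid,
        "passed": audit_report.passed,
        "n_records": audit_report.n_records,
        "failures": [list(f) for f in audit_report.failures],
        "log_valid": log_ok,
    }
    report.stages.append("audit")
    if not (chain_report.valid and audit_report.passed and log_ok):
        detail = ", ".join(f"{rid}: {why}" for rid, why in audit_report.failures)
        raise PipelineIntegrityError("audit", detail or "chain invalid")

    # stage 6: decryption (timed) + byte-equality assertion
    def _decrypt_all() -> Dict[str, bytes]:
        out: Dict[str, bytes] = {}
        for rid, data in storage.items():
            blocks = [[int(v) for v in b] for b in json.loads(data)]
            out[rid] = cipher.decrypt_record(blocks, priv, pub,
                                             chain=config.cipher_chaining)
        return out

    decrypted, t_dec = metrics.time_phase("decryption", _decrypt_all)
    for rid, data in plaintexts.items():
        if decrypted.get(rid) != data:
            raise PipelineIntegrityError("decrypt", f"record {rid} differs")
    report.decryption_ok = True
    report.stages.append("decrypt")

    decrypted_records = {rid: parse_record(d) for rid, d in decrypted.items()}
    train_parsed = [decrypted_records[r.patient_id] for r in train_recs]
    test_parsed = [decrypted_records[r.patient_id] for r in test_recs]
    X_tr, y_tr = feature_matrix(train_parsed)
    X_te, y_te = feature_matrix(test_parsed)
    if np.unique(y_tr).size < 2:
        raise PipelineIntegrityError("train", "single-class training data")

    # stage 7: train (baseline) or tune (AOA search) on the decrypted split
    net_cfg = replace(config.net_config or NetworkConfig(), seed=seeds[4],
                      batch_size=min((config.net_config or NetworkConfig()).batch_size,
                                     len(train_parsed)))
    if config.tune:
        spec = FitnessSpec(n_folds=config.n_folds, seed=seeds[5])
        best_hp, _, _ = search(X_tr, y_tr, config.search_space,
                               config.aoa_config, spec, net_cfg)
        net_cfg = replace(net_cfg,
                          learning_rate=best_hp.learning_rate,
                          momentum=best_hp.momentum,
                          epochs=best_hp.epochs,
                          dropout_rate=best_hp.dropout)
        report.hyperparameters = best_hp.to_dict()
    else:
        report.hyperparameters = {
            "learning_rate": net_cfg.learning_rate,
            "momentum": net_cfg.momentum,
            "epochs": net_cfg.epochs,
            "dropout": net_cfg.dropout_rate,
        }
    params, train_report = train(net_cfg, X_tr, y_tr, X_te, y_te)
    report.training = {
        "final_train_accuracy": train_report.train_accuracy[-1],
        "final_val_accuracy": train_report.val_accuracy[-1],
        "epochs": net_cfg.epochs,
    }
    report.stages.append("train")

    # stage 8: prediction on the held-out split
    labels, probs = predict(params, X_te)
    report.stages.append("predict")

    # stage 9: evaluation metrics
    counts = metrics.confusion_from_labels(y_te, labels)
    report.metrics = {
        "confusion": {"tp": counts.tp, "fp": counts.fp,
                      "tn": counts.tn, "fn": counts.fn},
        "precision": metrics.precision(counts),
        "accuracy": metrics.accuracy(counts),
        "recall": metrics.recall(counts),
        "recall_paper_dialect": metrics.recall(counts, dialect="paper"),
        "f1": metrics.f1(counts),
    }
    report.stages.append("metrics")

    # stage 10: alerts for predicted-abnormal patients
    ts = next(logical_clock)
    for rec, label, prob in zip(test_parsed, labels, probs[:, 1]):
        if label == 1:
            report.alerts.append(AlertMessage(
                patient_id=rec.patient_id, predicted_class=1,
                probability=float(prob), timestamp=ts,
            ).to_dict())
    report.stages.append("alert")

    report.hardware_dependent = {
        "key_generation_seconds": t_key.duration,
        "encryption_seconds": t_enc.duration,
        "decryption_seconds": t_dec.duration,
    }
    return report
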