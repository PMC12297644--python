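"""Merkle-tree commitments and a hash-chained block ledger with audit roles.

Encrypted patient records are committed to blocks: each block header links
to its predecessor by hash and carries a SHA-256 Merkle root over the
records' digests, so any byte-level tampering — in a stored record, a block
header, or the chain order — is immediately detectable.  Four roles from
the secured-storage design are modeled in-process: data storage (the
record-ID → ciphertext map), audit (re-verifying digests and Merkle
membership), log generation (a hash-chained audit log), and log checking.

Conventions: SHA-256 throughout; odd nodes duplicated per level (Bitcoin
convention); leaf hashes prefixed 0x00 and internal nodes 0x01 so an
internal node cannot be replayed as a leaf (second-preimage domain
separation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

__all__ = [
    "MerkleTree",
    "merkle_root",
    "merkle_proof",
    "verify_proof",
    "Block",
    "block_hash",
    "append_block",
    "verify_chain",
    "ChainReport",
    "AuditReport",
    "audit",
    "AuditLog",
    "generate_log",
    "check_log",
    "chain_to_jsonl",
    "chain_from_jsonl",
]

GENESIS_HASH = b"\x00" * 32

_LEAF_PREFIX = b"\x00"
_NODE_PREFIX = b"\x01"


def _sha(data: bytes) -> bytes:
    return hashlib.sha256(data).digest()


def _leaf_hash(leaf: bytes) -> bytes:
    return _sha(_LEAF_PREFIX + leaf)


def _node_hash(left: bytes, right: bytes) -> bytes:
    return _sha(_NODE_PREFIX + left + right)


class MerkleTree:
    """Merkle tree over an ordered list of byte-string leaves."""

    def __init__(self, leaves: Sequence[bytes]):
        if not leaves:
            raise ValueError("at least one leaf is required")
        level = [_leaf_hash(leaf) for leaf in leaves]
        self.levels: List[List[bytes]] = [level]
        while len(level) > 1:
            if len(level) % 2 == 1:
                level = level + [level[-1]]  # duplicate odd node
            level = [
                _node_hash(level[i], level[i + 1]) for i in range(0, len(level), 2)
            ]
            self.levels.append(level)

    @property
    def root(self) -> bytes:
        return self.levels[-1][0]

    def proof(self, index: int) -> List[Tuple[bytes, str]]:
        """Inclusion proof for leaf ``index``: (sibling digest, side) pairs,
        side being which side the *sibling* sits on ('L' or 'R')."""
        if not (0 <= index < len(self.levels[0])):
            raise IndexError(f"leaf index {index} out of range")
        path: List[Tuple[bytes, str]] = []
        idx = index
        for level in self.levels[:-1]:
            nodes = level if len(level) % 2 == 0 else level + [level[-1]]
            sib = idx ^ 1
            side = "L" if sib < idx else "R"
            path.append((nodes[sib], side))
            idx //= 2
        return path


def merkle_root(leaves: Sequence[bytes]) -> bytes:
    return MerkleTree(leaves).root


def merkle_proof(leaves: Sequence[bytes], index: int) -> List[Tuple[bytes, str]]:
    return MerkleTree(leaves).proof(index)


def verify_proof(
    leaf: bytes, index: int, proof: Sequence[Tuple[bytes, str]], root: bytes
) -> bool:
    """True iff ``leaf`` at ``index`` hashes up through ``proof`` to ``root``."""
    if index < 0:
        return False
    h = _leaf_hash(leaf)
    for sibling, side in proof:
        h = _node_hash(sibling, h) if side == "L" else _node_hash(h, sibling)
    return h == root


@dataclass
class Block:
    """Ledger block: header fields plus encrypted-record references."""

    index: int
    prev_hash: bytes
    merkle_root: bytes
    timestamp: int  # integer seconds
    nonce: int  # random tag, no proof-of-work
    payload: List[Tuple[str, bytes]]  # (record_id, sha256 of ciphertext)

    def serialize(self) -> bytes:
        """Canonical byte layout: index (8B BE) | prev_hash (32B) |
        merkle_root (32B) | timestamp (8B BE) | nonce (8B BE) |
        n_records (4B BE) | per record: id_len (2B BE) | id utf-8 |
        digest (32B)."""
        out = bytearray()
        out += self.index.to_bytes(8, "big")
        out += self.prev_hash
        out += self.merkle_root
        out += self.timestamp.to_bytes(8, "big")
        out += self.nonce.to_bytes(8, "big")
        out += len(self.payload).to_bytes(4, "big")
        for rid, digest in self.payload:
            rid_b = rid.encode("utf-8")
            out += len(rid_b).to_bytes(2, "big")
            out += rid_b
            out += digest
        return bytes(out)


def block_hash(block: Block) -> bytes:
    return _sha(block.serialize())


def append_block(
    chain: List[Block],
    cipher_records: Sequence[Tuple[str, bytes]],
    clock: Callable[[], float],
    nonce_rng,
) -> List[Block]:
    """Append a block committing ``cipher_records`` (id, ciphertext bytes).

    The Merkle tree is built over the records' SHA-256 digests; the genesis
    block links to 32 zero bytes.  ``nonce_rng`` is any object with an
    ``integers`` method (a numpy Generator).
    """
    if not cipher_records:
        raise ValueError("cipher_records must be non-empty")
    digests = [(rid, _sha(data)) for rid, data in cipher_records]
    root = merkle_root([d for _, d in digests])
    prev = block_hash(chain[-1]) if chain else GENESIS_HASH
    block = Block(
        index=len(chain),
        prev_hash=prev,
        merkle_root=root,
        timestamp=int(clock()),
        nonce=int(nonce_rng.integers(0, 2**62)),
        payload=digests,
    )
    chain.append(block)
    return chain


@dataclass
class ChainReport:
    valid: bool
    first_bad_index: int | None = None


def verify_chain(chain: Sequence[Block]) -> ChainReport:
    """Recompute linkage and Merkle roots; report the first failing block."""
    prev = GENESIS_HASH
    for i, block in enumerate(chain):
        ok = (
            block.index == i
            and block.prev_hash == prev
            and block.merkle_root == merkle_root([d for _, d in block.payload])
        )
        if not ok:
            return ChainReport(valid=False, first_bad_index=i)
        prev = block_hash(block)
    return ChainReport(valid=True)


@dataclass
class AuditReport:
    passed: bool
    n_records: int
    failures: List[Tuple[str, str]] = field(default_factory=list)  # (id, reason)


def audit(chain: Sequence[Block], storage: Dict[str, bytes]) -> AuditReport:
    """Third-party-auditor role: re-derive each stored record's digest and
    check Merkle membership in its block.  Missing or altered records are
    reported per ID and fail the audit."""
    failures: List[Tuple[str, str]] = []
    n = 0
    for block in chain:
        digests = [d for _, d in block.payload]
        tree = MerkleTree(digests)
        for pos, (rid, digest) in enumerate(block.payload):
            n += 1
            if rid not in storage:
                failures.append((rid, "missing from storage"))
                continue
            actual = _sha(storage[rid])
            if actual != digest:
                failures.append((rid, "digest mismatch"))
                continue
            if not verify_proof(actual, pos, tree.proof(pos), block.merkle_root):
                failures.append((rid, "merkle membership failed"))
    return AuditReport(passed=not failures, n_records=n, failures=failures)


@dataclass
class AuditLog:
    """Hash-chained audit log; each entry commits to its predecessor."""

    entries: List[dict] = field(default_factory=list)

    def _entry_hash(self, entry_core: dict, prev_hash: str) -> str:
        payload = json.dumps(
            {"prev": prev_hash, **entry_core}, sort_keys=True, separators=(",", ":")
        ).encode()
        return _sha(payload).hex()


def generate_log(
    report: AuditReport, log: AuditLog, timestamp: int, block_index: int = -1
) -> AuditLog:
    """Log-generator role: append the audit verdict as a hash-chained entry."""
    prev = log.entries[-1]["entry_hash"] if log.entries else "0" * 64
    core = {
        "timestamp": int(timestamp),
        "block_index": int(block_index),
        "verdict": "pass" if report.passed else "fail",
        "n_records": report.n_records,
        "failures": [list(f) for f in report.failures],
    }
    entry = dict(core)
    entry["prev_hash"] = prev
    entry["entry_hash"] = log._entry_hash(core, prev)
    log.entries.append(entry)
    return log


def check_log(log: AuditLog) -> bool:
    """Log-checker role: True iff every entry's hash chain validates."""
    prev = "0" * 64
    for entry in log.entries:
        core = {k: v for k, v in entry.items() if k not in ("prev_hash", "entry_hash")}
        if entry.get("prev_hash") != prev:
            return False
        if entry.get("entry_hash") != log._entry_hash(core, prev):
            return False
        prev = entry["entry_hash"]
    return True


def chain_to_jsonl(chain: Sequence[Block]) -> str:
    """One block per line, hex digests."""
    lines = []
    for b in chain:
        lines.append(json.dumps({
            "index": b.index,
            "prev_hash": b.prev_hash.hex(),
            "merkle_root": b.merkle_root.hex(),
            "timestamp": b.timestamp,
            "nonce": b.nonce,
            "payload": [[rid, d.hex()] for rid, d in b.payload],
        }, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")


def chain_from_jsonl(text: str) -> List[Block]:
    chain: List[Block] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        chain.append(Block(
            index=obj["index"],
            prev_hash=bytes.fromhex(obj["prev_hash"]),
            merkle_root=bytes.fromhex(obj["merkle_root"]),
            timestamp=obj["timestamp"],
            nonce=obj["nonce"],
            payload=[(rid, bytes.fromhex(d)) for rid, d in obj["payload"]],
        ))
    return chain
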