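"""Reproducibility tokens.

A token is a single URL-safe string that self-contains everything needed to
re-establish a prior analysis: every outcome-affecting setting, the pathway
and interaction database version tags, and the MD5 digest of the uploaded
dataset.  Encoding is canonical (sorted keys, fixed number formatting), so
equal inputs always give byte-identical tokens on any platform.  A CRC32 of
the payload is embedded and the decoded bytes are re-encoded and compared
against the incoming string, so any single-character corruption is detected
deterministically rather than silently accepted.
"""

from __future__ import annotations

import base64
import json
import re
import zlib
from dataclasses import dataclass, field

from .errors import SchemaVersionError, TokenError, ValidationError
from .io import DatasetFile

SCHEMA_VERSION = 1

#: Every outcome-affecting setting a token must carry, with defaults.
SETTINGS_SCHEMA: dict[str, object] = {
    "missing_cutoff": 0.34,
    "missing_scope": "overall",
    "contrast_a": "",
    "contrast_b": "",
    "paired": False,
    "de_engine": "moderated_t",
    "query_threshold": 0.05,
    "query_direction": "both",
    "background_mode": "universe",
    "min_pathway_size": 3,
    "max_pathway_size": 500,
    "network_score_cutoff": 400,
    "id_policy": "first",
    "seed": 0,
}

_DIGEST_RE = re.compile(r"^[0-9a-f]{32}$")


@dataclass
class SessionToken:
    """Decoded token payload."""

    settings: dict
    db_versions: dict[str, str]
    dataset_digest: str
    schema_version: int = SCHEMA_VERSION


def _canonical(value):
    """Normalize numbers so 1 and 1.0 serialize identically."""
    if isinstance(value, dict):
        return {k: _canonical(value[k]) for k in sorted(value)}
    if isinstance(value, bool):
        return value
    if isinstance(value, float) and value.is_integer():
        return int(value)
    return value


def fill_settings(settings: dict) -> dict:
    """Complete partial settings with schema defaults; reject unknown keys."""
    unknown = set(settings) - set(SETTINGS_SCHEMA)
    if unknown:
        raise ValidationError(f"unknown settings: {sorted(unknown)}")
    full = dict(SETTINGS_SCHEMA)
    full.update(settings)
    return full


def encode_token(
    settings: dict, db_versions: dict[str, str], dataset_digest: str
) -> str:
    """Serialize settings + database versions + dataset digest to a token.

    All schema keys must be present (use :func:`fill_settings` to apply
    defaults); a missing key is a completeness error listing what is absent.
    """
    missing = sorted(set(SETTINGS_SCHEMA) - set(settings))
    if missing:
        raise ValidationError(f"settings incomplete, missing keys: {missing}")
    if not _DIGEST_RE.match(dataset_digest):
        raise ValidationError(
            "dataset_digest must be 32 lowercase hex characters"
        )
    payload = _canonical(
        {
            "schema_version": SCHEMA_VERSION,
            "settings": fill_settings(settings),
            "db_versions": dict(db_versions),
            "dataset_digest": dataset_digest,
        }
    )
    body = json.dumps(payload, sort_keys=True, separators=(",", ":")).encode()
    crc = zlib.crc32(body) & 0xFFFFFFFF
    framed = crc.to_bytes(4, "big") + body
    compressed = zlib.compress(framed, level=9)
    return base64.urlsafe_b64encode(compressed).decode("ascii").rstrip("=")


def decode_token(token: str) -> SessionToken:
    """Exact inverse of :func:`encode_token`.

    Raises :class:`TokenError` on any corruption (bad base64, failed
    decompression, CRC mismatch, or a non-canonical encoding of the same
    payload) and :class:`SchemaVersionError` on an unknown schema version.
    """
    if not token:
        raise TokenError("empty token")
    pad = "=" * (-len(token) % 4)
    try:
        compressed = base64.urlsafe_b64decode(token + pad)
        framed = zlib.decompress(compressed)
    except Exception as exc:
        raise TokenError(f"token is not decodable: {exc}") from exc
    if len(framed) < 5:
        raise TokenError("token payload truncated")
    crc, body = int.from_bytes(framed[:4], "big"), framed[4:]
    if zlib.crc32(body) & 0xFFFFFFFF != crc:
        raise TokenError("token checksum mismatch: payload corrupted")
    # round-trip guard: catches corruption hiding in base64 trailing bits
    reencoded = base64.urlsafe_b64encode(zlib.compress(framed, level=9))
    if reencoded.decode("ascii").rstrip("=") != token:
        raise TokenError("token is not in canonical form")
    try:
        payload = json.loads(body.decode())
    except Exception as exc:
        raise TokenError(f"token payload is not valid JSON: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported token schema version {version!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    return SessionToken(
        settings=payload["settings"],
        db_versions=payload["db_versions"],
        dataset_digest=payload["dataset_digest"],
        schema_version=version,
    )


@dataclass
class DatasetMatchReport:
    match: bool
    token_digest: str
    dataset_digest: str
    warning: str = ""


def verify_dataset(token: SessionToken, dataset: DatasetFile) -> DatasetMatchReport:
    """Compare the token's recorded dataset digest against an uploaded file.

    Identity is byte-level (the file name is not hashed).  On mismatch the
    analysis may proceed, but the warning is mandatory in any output.
    """
    match = token.dataset_digest == dataset.digest
    warning = (
        ""
        if match
        else (
            "WARNING: the uploaded dataset is not identical to the file used "
            f"in the previous session (token {token.dataset_digest}, "
            f"upload {dataset.digest}); results may differ"
        )
    )
    return DatasetMatchReport(
        match=match,
        token_digest=token.dataset_digest,
        dataset_digest=dataset.digest,
        warning=warning,
    )
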