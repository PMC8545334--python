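"""Reproducibility tokens: freeze settings + database versions + data digest.

A token is a single URL-safe string.  Decoding it restores every
outcome-affecting setting; the embedded MD5 digest warns when the uploaded
file differs from the one analysed originally.
"""

import tempfile
from pathlib import Path

from proteoflow import (
    DatasetFile,
    decode_token,
    encode_token,
    fill_settings,
    verify_dataset,
)

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "abundances.tsv"
    data.write_text("id\ts1\ts2\nP12345\t25.1\t24.8\nQ9Y6K9\t22.0\t22.4\n")
    dataset = DatasetFile.from_path(data)

    settings = fill_settings({"contrast_a": "ctrl", "contrast_b": "treated",
                              "missing_cutoff": 0.25, "seed": 42})
    token = encode_token(settings, {"pathway": "v85", "interaction": "v11.5"},
                         dataset.digest)
    print(f"token ({len(token)} chars): {token}")

    decoded = decode_token(token)
    print(f"decoded contrast: {decoded.settings['contrast_a']} vs "
          f"{decoded.settings['contrast_b']}, "
          f"db versions {decoded.db_versions}")

    print("same file:", "match" if verify_dataset(decoded, dataset).match
          else "mismatch")

    data.write_text("id\ts1\ts2\nP12345\t25.1\t24.9\nQ9Y6K9\t22.0\t22.4\n")
    report = verify_dataset(decoded, DatasetFile.from_path(data))
    print("after editing one value:",
          "match" if report.match else "mismatch")
    print(report.warning)
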