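"""In-memory short-read container with FASTQ I/O.

Reads are held as a dense (n_reads x read_len) matrix of 2-bit base codes so
that k-mer counting and exact placement stay vectorized; FASTQ text is only
materialized at the file boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ._encode import codes_to_seq, seq_to_codes


class ReadSet:
    """Uniform-length reads as a code matrix plus optional phred qualities."""

    def __init__(self, codes: np.ndarray, quals: np.ndarray | None = None,
                 ids: list[str] | None = None):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2:
            raise ValueError("read codes must be a (n_reads, read_len) matrix")
        if quals is not None:
            quals = np.asarray(quals, dtype=np.uint8)
            if quals.shape != codes.shape:
                raise ValueError("quality matrix shape mismatch")
        if ids is not None and len(ids) != codes.shape[0]:
            raise ValueError("id list length mismatch")
        self.codes = codes
        self.quals = quals
        self.ids = ids

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_len(self) -> int:
        return self.codes.shape[1]

    def total_bases(self) -> int:
        return self.codes.size

    def sequences(self):
        """Yield read sequences as strings."""
        for row in self.codes:
            yield codes_to_seq(row)

    def subset(self, index: np.ndarray) -> "ReadSet":
        ids = [self.ids[i] for i in index] if self.ids is not None else None
        return ReadSet(
            self.codes[index],
            self.quals[index] if self.quals is not None else None,
            ids,
        )

    @classmethod
    def from_sequences(cls, seqs: list[str],
                       quals: list[str] | None = None,
                       ids: list[str] | None = None) -> "ReadSet":
        if not seqs:
            return cls(np.empty((0, 0), dtype=np.uint8))
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("ReadSet requires uniform read length")
        codes = np.vstack([seq_to_codes(s) for s in seqs])
        qmat = None
        if quals is not None:
            qmat = np.vstack([
                np.frombuffer(q.encode("ascii"), dtype=np.uint8) - 33
                for q in quals
            ])
        return cls(codes, qmat, ids)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        seqs: list[str] = []
        quals: list[str] = []
        ids: list[str] = []
        with open(path) as fh:
            while True:
                header = fh.readline().rstrip("\n")
                if not header:
                    break
                if not header.startswith("@"):
                    raise ValueError(f"{path}: malformed FASTQ header {header!r}")
                seq = fh.readline().rstrip("\n")
                fh.readline()  # separator
                qual = fh.readline().rstrip("\n")
                if len(qual) != len(seq):
                    raise ValueError(f"{path}: quality length mismatch")
                ids.append(header[1:].split()[0])
                seqs.append(seq.upper())
                quals.append(qual)
        return cls.from_sequences(seqs, quals, ids)

    def to_fastq(self, path: str | Path, chunk: int = 100_000) -> None:
        qual_default = "I" * self.read_len  # phred 40
        with open(path, "w") as fh:
            for start in range(0, self.n_reads, chunk):
                lines: list[str] = []
                for i in range(start, min(start + chunk, self.n_reads)):
                    name = self.ids[i] if self.ids is not None else f"read{i}"
                    if self.quals is not None:
                        qual = "".join(chr(q + 33) for q in self.quals[i])
                    else:
                        qual = qual_default
                    lines.append(
                        f"@{name}\n{codes_to_seq(self.codes[i])}\n+\n{qual}"
                    )
                fh.write("\n".join(lines) + "\n")
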