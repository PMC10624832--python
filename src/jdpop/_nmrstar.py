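"""Minimal NMR-STAR v3 reader for assigned-chemical-shift loops.

Only what the pipeline needs from a BMRB download: the ``_Atom_chem_shift``
loop of an assigned-chemical-shift saveframe (sequence position, residue
type, atom name, shift value and optional uncertainty).  STAR quoting rules
(single/double quotes, semicolon-delimited text blocks) are honoured during
tokenization; everything outside the target loop is skipped.
"""

from __future__ import annotations

from pathlib import Path


class StarParseError(ValueError):
    pass


def _tokenize(text: str):
    """Yield (token, lineno), handling ', \", and ;-delimited multiline values."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            # semicolon-delimited block; consume until closing ';'
            block = []
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            if i >= len(lines):
                raise StarParseError(f"unterminated ';' block starting near line {i}")
            yield "\n".join(block), i + 1
            i += 1
            continue
        pos = 0
        n = len(line)
        while pos < n:
            while pos < n and line[pos] in " \t":
                pos += 1
            if pos >= n or line[pos] == "#":
                break
            if line[pos] in "'\"":
                quote = line[pos]
                end = pos + 1
                # closing quote must be followed by whitespace or EOL
                while end < n:
                    if line[end] == quote and (end + 1 == n or line[end + 1] in " \t"):
                        break
                    end += 1
                if end >= n:
                    raise StarParseError(f"unterminated quote on line {i + 1}")
                yield line[pos + 1 : end], i + 1
                pos = end + 1
            else:
                end = pos
                while end < n and line[end] not in " \t":
                    end += 1
                yield line[pos:end], i + 1
                pos = end
        i += 1


# column name -> output key; BMRB v3.1 Atom_chem_shift tags
_WANTED = {
    "Seq_ID": "seq_id",
    "Comp_index_ID": "seq_id",  # fallback numbering tag
    "Comp_ID": "comp_id",
    "Atom_ID": "atom_id",
    "Val": "val",
    "Val_err": "val_err",
}


def read_atom_chem_shift_loop(path: str | Path) -> list[dict]:
    """Extract rows of the first ``_Atom_chem_shift`` loop in the file.

    Returns dicts with keys ``seq_id``, ``comp_id``, ``atom_id``, ``val`` and
    (when present and not '.') ``val_err``.
    """
    text = Path(path).read_text()
    tokens = list(_tokenize(text))
    k = 0
    while k < len(tokens):
        tok, lineno = tokens[k]
        if tok == "loop_":
            tags: list[str] = []
            j = k + 1
            while j < len(tokens) and tokens[j][0].startswith("_"):
                tags.append(tokens[j][0])
                j += 1
            if tags and all(t.startswith("_Atom_chem_shift.") for t in tags):
                return _parse_loop_rows(tokens, j, tags, lineno)
            k = j
        else:
            k += 1
    raise StarParseError(f"{path}: no _Atom_chem_shift loop found")


def _parse_loop_rows(tokens, start, tags, loop_lineno) -> list[dict]:
    names = [t.split(".", 1)[1] for t in tags]
    ncol = len(names)
    values = []
    j = start
    while j < len(tokens) and tokens[j][0] not in ("stop_", "loop_") and not tokens[j][0].startswith(
        "save_"
    ):
        values.append(tokens[j])
        j += 1
    if len(values) % ncol != 0:
        raise StarParseError(
            f"loop at line {loop_lineno}: {len(values)} values not divisible by {ncol} columns"
        )
    rows = []
    for r in range(0, len(values), ncol):
        raw = dict(zip(names, (v for v, _ in values[r : r + ncol])))
        row: dict = {}
        for col, key in _WANTED.items():
            if col in raw and key not in row:
                row[key] = raw[col]
        missing = [k for k in ("seq_id", "comp_id", "atom_id", "val") if k not in row]
        if missing:
            raise StarParseError(
                f"loop at line {loop_lineno}: missing required tags for {missing}"
            )
        err = row.get("val_err")
        row["val_err"] = None if err in (None, ".", "?") else float(err)
        rows.append(row)
    return rows
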