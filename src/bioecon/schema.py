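"""Structural validation of report documents against the shipped schema.

Implements the small subset of JSON Schema the report schema uses —
``type``, ``required``, ``properties``, ``items``, ``enum`` and local
``$ref`` into ``$defs`` — so reports can be checked without any external
schema library.
"""

from __future__ import annotations

import json
from importlib import resources

from .errors import SchemaError

__all__ = ["load_schema", "validate_report"]

_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def load_schema() -> dict:
    """The report JSON schema shipped with the package."""
    text = resources.files("bioecon").joinpath("report_schema.json").read_text("utf-8")
    return json.loads(text)


def _type_ok(value, name: str) -> bool:
    if name == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if name == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    return isinstance(value, _TYPE_MAP[name])


def _resolve(node: dict, root: dict) -> dict:
    ref = node.get("$ref")
    if ref is None:
        return node
    if not ref.startswith("#/"):
        raise SchemaError(f"only local $ref supported, got {ref!r}")
    out = root
    for part in ref[2:].split("/"):
        out = out[part]
    return out


def _check(value, node: dict, root: dict, path: str, errors: list[str]) -> None:
    node = _resolve(node, root)
    types = node.get("type")
    if types is not None:
        names = [types] if isinstance(types, str) else list(types)
        if not any(_type_ok(value, t) for t in names):
            errors.append(f"{path}: expected {'|'.join(names)}, got {type(value).__name__}")
            return
    if "enum" in node and value not in node["enum"]:
        errors.append(f"{path}: {value!r} not in {node['enum']}")
    if isinstance(value, dict):
        for key in node.get("required", ()):
            if key not in value:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in node.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, root, f"{path}.{key}", errors)
    if isinstance(value, list) and "items" in node:
        for i, item in enumerate(value):
            _check(item, node["items"], root, f"{path}[{i}]", errors)


def validate_report(document: dict, schema: dict | None = None) -> None:
    """Raise :class:`SchemaError` listing every structural violation."""
    schema = schema if schema is not None else load_schema()
    errors: list[str] = []
    _check(document, schema, schema, "$", errors)
    if errors:
        raise SchemaError("report does not match schema:\n  " + "\n  ".join(errors))
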