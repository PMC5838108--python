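"""Assemble, manifest, serve and (dry-run) publish a browsable data bundle.

A site bundle is a self-contained directory: viewer assets at the root (a
shipped template, or a minimal placeholder page) and the tidy data bundle
under ``data/``, from which a viewer application reads it.  A SHA-256
manifest makes the bundle content-addressable, so republications of
unchanged data are byte-identical and any edit is pinpointed to the files
whose hashes moved.

Actual publication (git hosting, archival DOIs, central registries) is
network glue and out of core; :func:`publish_dryrun` emits the exact
artifacts that would be pushed -- a ready-to-init repository directory and
a registry payload JSON -- without any network traffic.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import socket
import threading
import warnings
from dataclasses import dataclass
from functools import partial
from http.server import SimpleHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Any

from .dataset import TractometryDataset, validate
from .io import TidyBundle, write_tidy

__all__ = [
    "SiteBundle",
    "ServerHandle",
    "assemble_site",
    "serve",
    "publish_dryrun",
    "PUBLISH_PAYLOAD_SCHEMA",
    "check_against_schema",
]

MANIFEST_FILE = "manifest.json"

_PLACEHOLDER_INDEX = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>Tractometry bundle</title></head>
<body>
<h1>Tractometry data bundle</h1>
<p>This is a placeholder page. The tidy data tables live under
<a href="data/">data/</a>: nodes.csv, subjects.csv, subjects.json,
params.json.</p>
</body>
</html>
"""


@dataclass(frozen=True)
class SiteBundle:
    """Handle to an assembled site directory plus its manifest."""

    root: Path
    manifest: dict[str, dict[str, Any]]

    @property
    def data_dir(self) -> Path:
        return self.root / "data"

    @property
    def manifest_path(self) -> Path:
        return self.root / MANIFEST_FILE

    def verify(self) -> list[str]:
        """Return a list of manifest violations (empty iff intact)."""
        problems = []
        listed = set(self.manifest)
        for rel, entry in self.manifest.items():
            f = self.root / rel
            if not f.is_file():
                problems.append(f"missing file: {rel}")
                continue
            if f.stat().st_size != entry["size"]:
                problems.append(f"size mismatch: {rel}")
            if _sha256(f) != entry["sha256"]:
                problems.append(f"hash mismatch: {rel}")
        on_disk = {
            str(p.relative_to(self.root))
            for p in self.root.rglob("*")
            if p.is_file() and p.name != MANIFEST_FILE
        }
        for rel in sorted(on_disk - listed):
            problems.append(f"unlisted file: {rel}")
        return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_manifest(root: Path) -> dict[str, dict[str, Any]]:
    manifest = {}
    for p in sorted(root.rglob("*")):
        if p.is_file() and p.name != MANIFEST_FILE:
            rel = str(p.relative_to(root)).replace("\\", "/")
            manifest[rel] = {"size": p.stat().st_size, "sha256": _sha256(p)}
    return manifest


def assemble_site(
    ds: TractometryDataset,
    outdir: str | Path,
    template_dir: str | Path | None = None,
    overwrite: bool = False,
) -> SiteBundle:
    """Arrange a dataset and viewer assets into a publishable directory.

    Copies ``template_dir`` (or writes a minimal placeholder ``index.html``
    when none is given), writes the tidy bundle under ``data/`` and a
    SHA-256 manifest at the root.  Assembly is deterministic: re-assembling
    an unchanged dataset reproduces identical hashes.
    """
    report = validate(ds)
    if not report.valid:
        msgs = "; ".join(f.message for f in report.errors)
        raise ValueError(f"refusing to assemble invalid dataset: {msgs}")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if template_dir is not None:
        shutil.copytree(template_dir, outdir, dirs_exist_ok=True)
    else:
        (outdir / "index.html").write_text(_PLACEHOLDER_INDEX, encoding="utf-8")

    write_tidy(ds, outdir / "data")
    manifest = _build_manifest(outdir)
    (outdir / MANIFEST_FILE).write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return SiteBundle(root=outdir, manifest=manifest)


def load_site(root: str | Path) -> SiteBundle:
    """Re-open an assembled bundle from its manifest."""
    root = Path(root)
    manifest = json.loads((root / MANIFEST_FILE).read_text(encoding="utf-8"))
    return SiteBundle(root=root, manifest=manifest)


# ---------------------------------------------------------------------------
# local static server
# ---------------------------------------------------------------------------

class ServerHandle:
    """Running local static HTTP server over a bundle directory."""

    def __init__(self, server: ThreadingHTTPServer, thread: threading.Thread):
        self._server = server
        self._thread = thread

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    @property
    def url(self) -> str:
        return f"http://localhost:{self.port}/"

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        self._thread.join(timeout=5)

    def __enter__(self) -> "ServerHandle":
        return self

    def __exit__(self, *exc: object) -> None:
        self.stop()


class _QuietHandler(SimpleHTTPRequestHandler):
    def log_message(self, fmt: str, *args: Any) -> None:  # silence request log
        pass


def serve(bundle_dir: str | Path, port: int = 8080, max_tries: int = 50) -> ServerHandle:
    """Serve a bundle directory over local HTTP until stopped.

    If ``port`` is taken the next free port is used, with a warning; the
    chosen port is available on the returned handle.
    """
    bundle_dir = Path(bundle_dir)
    if not bundle_dir.is_dir():
        raise FileNotFoundError(bundle_dir)
    handler = partial(_QuietHandler, directory=str(bundle_dir))
    last_exc: OSError | None = None
    for candidate in range(port, port + max_tries):
        try:
            server = ThreadingHTTPServer(("127.0.0.1", candidate), handler)
            break
        except OSError as exc:
            last_exc = exc
    else:
        raise OSError(f"no free port in [{port}, {port + max_tries})") from last_exc
    if server.server_address[1] != port:
        warnings.warn(
            f"port {port} in use; serving on {server.server_address[1]} instead",
            stacklevel=2,
        )
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return ServerHandle(server, thread)


# ---------------------------------------------------------------------------
# publish dry-run
# ---------------------------------------------------------------------------

#: Schema of the registry payload emitted by :func:`publish_dryrun`
#: (JSON-Schema subset: type / required / properties / items).
PUBLISH_PAYLOAD_SCHEMA: dict[str, Any] = {
    "type": "object",
    "required": [
        "title",
        "n_subjects",
        "n_tracts",
        "n_nodes",
        "metrics",
        "tracts",
        "params",
        "manifest_sha256",
    ],
    "properties": {
        "title": {"type": "string"},
        "n_subjects": {"type": "integer"},
        "n_tracts": {"type": "integer"},
        "n_nodes": {"type": "integer"},
        "metrics": {"type": "array", "items": {"type": "string"}},
        "tracts": {"type": "array", "items": {"type": "string"}},
        "metadata_columns": {"type": "array", "items": {"type": "string"}},
        "params": {"type": "object"},
        "manifest_sha256": {"type": "string"},
    },
}

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def check_against_schema(obj: Any, schema: dict[str, Any], path: str = "$") -> list[str]:
    """Validate ``obj`` against the JSON-Schema subset used by this package.

    Supports ``type``, ``required``, ``properties`` and ``items``; returns a
    list of violation messages (empty iff valid).
    """
    problems: list[str] = []
    t = schema.get("type")
    if t is not None:
        py = _TYPES[t]
        ok = isinstance(obj, py) and not (t in ("integer", "number") and isinstance(obj, bool))
        if not ok:
            problems.append(f"{path}: expected {t}, got {type(obj).__name__}")
            return problems
    if isinstance(obj, dict):
        for req in schema.get("required", []):
            if req not in obj:
                problems.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                problems += check_against_schema(obj[key], sub, f"{path}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            problems += check_against_schema(item, schema["items"], f"{path}[{i}]")
    return problems


def publish_dryrun(bundle: SiteBundle, outdir: str | Path, title: str = "Tractometry dataset") -> dict[str, Path]:
    """Emit publish artifacts without touching the network.

    Produces under ``outdir``:

    * ``repo/`` -- a byte-for-byte copy of the bundle, ready for
      ``git init`` and push to any static host;
    * ``payload.json`` -- the dataset summary that would be registered with
      a central index (subject/tract/metric counts, params, manifest hash);
    * ``payload.schema.json`` -- the schema the payload conforms to.

    The dry-run is idempotent: a second run reproduces identical artifacts.
    """
    problems = bundle.verify()
    if problems:
        raise ValueError(f"bundle fails manifest verification: {problems}")
    outdir = Path(outdir)
    repo = outdir / "repo"
    if repo.exists():
        shutil.rmtree(repo)
    shutil.copytree(bundle.root, repo)

    manifest_digest = hashlib.sha256(
        json.dumps(bundle.manifest, sort_keys=True).encode()
    ).hexdigest()
    subjects = json.loads((bundle.data_dir / "subjects.json").read_text(encoding="utf-8"))
    nodes_header = (bundle.data_dir / "nodes.csv").open(encoding="utf-8").readline().strip()
    metrics = nodes_header.split(",")[3:]
    tracts: list[str] = []
    n_nodes = 0
    with open(bundle.data_dir / "nodes.csv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            tract = line.split(",")[1]
            if tract not in tracts:
                tracts.append(tract)
            n_nodes = max(n_nodes, int(line.split(",")[2]) + 1)
    params = json.loads((bundle.data_dir / "params.json").read_text(encoding="utf-8"))
    meta_cols = sorted({k for rec in subjects for k in rec if k != "subjectID"})

    payload = {
        "title": title,
        "n_subjects": len(subjects),
        "n_tracts": len(tracts),
        "n_nodes": n_nodes,
        "metrics": metrics,
        "tracts": tracts,
        "metadata_columns": meta_cols,
        "params": params,
        "manifest_sha256": manifest_digest,
    }
    violations = check_against_schema(payload, PUBLISH_PAYLOAD_SCHEMA)
    if violations:
        raise AssertionError(f"payload fails its own schema: {violations}")

    outdir.mkdir(parents=True, exist_ok=True)
    payload_path = outdir / "payload.json"
    payload_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    schema_path = outdir / "payload.schema.json"
    schema_path.write_text(
        json.dumps(PUBLISH_PAYLOAD_SCHEMA, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {"repo": repo, "payload": payload_path, "schema": schema_path}
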