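"""Minimal WSGI snapshot-analysis service (stdlib only).

Endpoints:
  GET  /health   -> {"status": "ok", "model_id": ...}
  POST /analyze  -> JSON with n_pos, n_neg, percentage, percentage_defined,
                    model_id and the overlay as a base64 PNG data URI.
  GET  /         -> small HTML upload page.

Uploads may be a raw image body (Content-Type image/png, image/jpeg or
image/tiff) or multipart/form-data with an ``image`` field.  Responses are a
pure function of (checkpoint, uploaded bytes); no state is kept between
requests.
"""

from __future__ import annotations

import base64
import io
import json
from email.message import Message
from email.parser import BytesParser
from email.policy import default as default_email_policy
from wsgiref.simple_server import make_server

import numpy as np

from ..errors import PlasmaCountError
from ..network.model import load_checkpoint
from .snapshot import analyze_snapshot

_IMAGE_TYPES = {"image/png", "image/jpeg", "image/tiff"}

_INDEX_HTML = """<!doctype html>
<html><head><title>plasmacount</title></head><body>
<h1>Plasma-cell snapshot analysis</h1>
<form action="/analyze" method="post" enctype="multipart/form-data">
<input type="file" name="image"><input type="submit" value="Analyze">
</form></body></html>
"""


def _decode_image(body: bytes):
    from PIL import Image, UnidentifiedImageError

    try:
        img = Image.open(io.BytesIO(body))
        img.load()
    except UnidentifiedImageError as exc:
        raise ValueError("upload is not a decodable image") from exc
    return np.asarray(img.convert("RGB"))


def _parse_multipart(content_type: str, body: bytes) -> bytes:
    msg_bytes = (
        b"Content-Type: " + content_type.encode() + b"\r\nMIME-Version: 1.0\r\n\r\n" + body
    )
    msg: Message = BytesParser(policy=default_email_policy).parsebytes(msg_bytes)
    if not msg.is_multipart():
        raise ValueError("malformed multipart body")
    for part in msg.iter_parts():
        if part.get_param("name", header="content-disposition") == "image":
            return part.get_payload(decode=True)
    raise ValueError("multipart body has no 'image' field")


def create_app(checkpoint_path, pixel_size: float = 0.25, det_kwargs: dict | None = None):
    """Build the WSGI application around a loaded checkpoint."""
    network, normalizer, metadata = load_checkpoint(checkpoint_path)
    model_id = str(metadata.get("model_id", "plasmacount-checkpoint"))

    def respond(start_response, status: str, payload: dict | str, ctype="application/json"):
        body = (
            json.dumps(payload).encode()
            if ctype == "application/json"
            else payload.encode()
        )
        start_response(
            status,
            [("Content-Type", ctype), ("Content-Length", str(len(body)))],
        )
        return [body]

    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        if method == "GET" and path == "/health":
            return respond(start_response, "200 OK", {"status": "ok", "model_id": model_id})
        if method == "GET" and path == "/":
            return respond(start_response, "200 OK", _INDEX_HTML, ctype="text/html")
        if method == "POST" and path == "/analyze":
            try:
                length = int(environ.get("CONTENT_LENGTH") or 0)
                body = environ["wsgi.input"].read(length)
                ctype = environ.get("CONTENT_TYPE", "")
                if ctype.startswith("multipart/form-data"):
                    body = _parse_multipart(ctype, body)
                elif ctype and ctype.split(";")[0] not in _IMAGE_TYPES:
                    return respond(
                        start_response,
                        "415 Unsupported Media Type",
                        {"error": f"unsupported content type {ctype!r}"},
                    )
                image = _decode_image(body)
            except (ValueError, KeyError) as exc:
                return respond(start_response, "400 Bad Request", {"error": str(exc)})
            try:
                result = analyze_snapshot(
                    image, network, normalizer,
                    pixel_size=pixel_size, model_id=model_id, det_kwargs=det_kwargs,
                )
            except PlasmaCountError as exc:
                return respond(start_response, "422 Unprocessable Entity", {"error": str(exc)})
            from PIL import Image

            buf = io.BytesIO()
            Image.fromarray(result.overlay).save(buf, format="PNG")
            overlay_uri = "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()
            return respond(
                start_response,
                "200 OK",
                {
                    "n_pos": result.n_pos,
                    "n_neg": result.n_neg,
                    "percentage": result.percentage,
                    "percentage_defined": result.percentage_defined,
                    "pixel_size": result.pixel_size,
                    "model_id": result.model_id,
                    "overlay": overlay_uri,
                },
            )
        return respond(start_response, "404 Not Found", {"error": "not found"})

    return app


def serve(checkpoint_path, host: str = "127.0.0.1", port: int = 5000, **kwargs):
    """Run the service with the stdlib WSGI reference server (blocking)."""
    app = create_app(checkpoint_path, **kwargs)
    with make_server(host, port, app) as httpd:
        httpd.serve_forever()
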