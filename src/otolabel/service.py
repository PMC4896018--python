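"""HTTP label-serving endpoint.

A small REST service over the trained model bundle: clients POST one or more
report texts to ``/labels`` (or the versioned alias ``/v1/labels``) and get
back, in request order, the four predicted region labels per report plus
continuous abnormality scores where the model family provides them.
``GET /health`` reports service and bundle metadata.  The service is
stateless across requests.
"""

from __future__ import annotations

import json
import logging
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

from .corpus import REGIONS
from .modeling import Bundle, load_bundle, predict

__all__ = ["LabelService", "create_server", "serve"]

logger = logging.getLogger(__name__)


class LabelService:
    """Request validation and prediction over a loaded bundle."""

    def __init__(self, bundle: Bundle):
        missing = [r for r in REGIONS if r not in bundle.classifiers]
        if missing:
            raise ValueError(f"model bundle is missing regions: {missing}")
        self.bundle = bundle

    def health(self) -> dict:
        return {
            "status": "ok",
            "service": "otolabel",
            "api_version": "v1",
            "regions": list(REGIONS),
            "bundle": {
                "version": self.bundle.manifest.get("version"),
                "seed": self.bundle.manifest.get("seed"),
                "models": {r: m.get("algorithm")
                           for r, m in self.bundle.manifest.get("regions", {}).items()},
            },
        }

    def label_reports(self, payload) -> dict:
        """Validate a LabelRequest payload and predict.

        Raises ValueError with a client-facing message on malformed input.
        """
        if not isinstance(payload, dict) or "reports" not in payload:
            raise ValueError('request body must be {"reports": [...]}')
        reports = payload["reports"]
        if not isinstance(reports, list) or not reports:
            raise ValueError('"reports" must be a non-empty list')
        results = []
        for i, item in enumerate(reports):
            if not isinstance(item, dict) or not isinstance(item.get("text"), str) \
                    or not item["text"]:
                raise ValueError(
                    f"reports[{i}] must be an object with non-empty 'text'")
            report_id = item.get("report_id") or f"request-{i}"
            labels = {}
            scores = {}
            for region in REGIONS:
                label, score = predict(self.bundle.classifiers[region],
                                       item["text"])
                labels[region] = label
                if score is not None:
                    scores[region] = score
            results.append({"report_id": report_id, "labels": labels,
                            "scores": scores})
        return {"labels": results}


def _make_handler(service: LabelService):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, fmt, *args):  # route to logging, not stderr spam
            logger.debug("%s - %s", self.address_string(), fmt % args)

        def _send(self, status: int, body: dict) -> None:
            data = json.dumps(body).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def do_GET(self):
            if self.path.rstrip("/") in ("/health", "/v1/health"):
                self._send(200, service.health())
            else:
                self._send(404, {"error": f"unknown path {self.path}"})

        def do_POST(self):
            if self.path.rstrip("/") not in ("/labels", "/v1/labels"):
                self._send(404, {"error": f"unknown path {self.path}"})
                return
            try:
                length = int(self.headers.get("Content-Length") or 0)
                raw = self.rfile.read(length)
                payload = json.loads(raw or b"")
            except (ValueError, json.JSONDecodeError):
                self._send(400, {"error": "request body is not valid JSON"})
                return
            try:
                self._send(200, service.label_reports(payload))
            except ValueError as exc:
                self._send(400, {"error": str(exc)})
            except Exception:  # pragma: no cover - defensive
                logger.exception("labeling request failed")
                self._send(500, {"error": "internal error"})

    return Handler


def create_server(bundle: Bundle | str | Path, host: str = "127.0.0.1",
                  port: int = 0) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server for a bundle or bundle path."""
    if not isinstance(bundle, Bundle):
        bundle = load_bundle(bundle)
    service = LabelService(bundle)
    server = ThreadingHTTPServer((host, port), _make_handler(service))
    server.service = service  # type: ignore[attr-defined]
    return server


def serve(bundle_path: str | Path, host: str = "127.0.0.1",
          port: int = 8000) -> None:
    """Load the bundle and serve until interrupted."""
    server = create_server(bundle_path, host, port)
    logger.info("serving on http://%s:%d (POST /labels, GET /health)",
                *server.server_address)
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        pass
    finally:
        server.server_close()
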