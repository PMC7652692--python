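"""The three-call client-server wire contract.

The server exposes exactly three API calls::

    GET /round    -> current round number
    GET /weight   -> global weights (list-of-tensors JSON payload)
    PUT /weight   -> upload local weights (+ client id, round, sample count)

Two transports implement the same contract: an in-process loopback (used by
tests and simulated runs) and plain HTTP on the standard library's
``http.server`` / ``urllib``. Both pass weights through the identical
canonical JSON encoding, so a federation run is bit-identical across
transports given the same seeds.

The server manages a fixed, pre-registered client roster. By default a
round advances only when every expected client has submitted, so no client
is ever dropped from an aggregation; a fractional participation threshold
can lower that bar for ablation studies. A client that already participated
in the current round is told to wait for the next one.
"""

from __future__ import annotations

import json
import math
import threading
import time
from contextlib import contextmanager
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib import error as urlerror
from urllib import request as urlrequest

import numpy as np

from .federation import ClientUpdate, client_seed, fedavg
from .models import (
    ModelSpec,
    TrainingConfig,
    WeightSet,
    decode_payload,
    encode_payload,
    local_train,
)

__all__ = [
    "FederationServer",
    "LoopbackTransport",
    "HttpTransport",
    "participation_loop",
    "http_server",
    "ProtocolError",
]


class ProtocolError(RuntimeError):
    pass


class FederationServer:
    """Server-side round state machine behind the three API calls."""

    def __init__(
        self,
        spec: ModelSpec,
        initial_weights: WeightSet | None,
        expected_clients,
        max_rounds: int,
        weighting: str = "samples",
        participation_threshold: float = 1.0,
    ):
        self.spec = spec
        self.global_weights = initial_weights
        self.expected = frozenset(expected_clients)
        if not self.expected:
            raise ValueError("server needs a non-empty client roster")
        if not 0.0 < participation_threshold <= 1.0:
            raise ValueError("participation_threshold must be in (0, 1]")
        self.max_rounds = max_rounds
        self.weighting = weighting
        # fraction of the roster whose updates trigger aggregation; 1.0
        # (every expected client, none dropped) is the default contract
        self.participation_threshold = participation_threshold
        self.round_index = 0
        self.pending: dict[str, ClientUpdate] = {}
        self.aggregations = 0
        self._lock = threading.Lock()

    # -- the three calls --------------------------------------------------

    def get_round(self) -> int:
        with self._lock:
            return self.round_index

    def get_weight(self) -> dict:
        with self._lock:
            if self.global_weights is None:
                raise ProtocolError("uninitialized: no global weights yet")
            return self.global_weights.to_payload()

    def put_weight(self, client_id: str, round_index: int, payload: dict, n_k: int) -> dict:
        with self._lock:
            if client_id not in self.expected:
                return {"status": "unknown_client"}
            if self.round_index >= self.max_rounds:
                return {"status": "finished", "round": self.round_index}
            if round_index != self.round_index:
                return {"status": "stale_round", "round": self.round_index}
            if client_id in self.pending:
                return {"status": "already_participated", "round": self.round_index}
            try:
                weights = WeightSet.from_payload(payload)
            except (KeyError, TypeError, ValueError) as exc:
                return {"status": "invalid_payload", "detail": str(exc)}
            self.pending[client_id] = ClientUpdate(
                client_id, round_index, weights, int(n_k)
            )
            required = max(
                1, math.ceil(self.participation_threshold * len(self.expected))
            )
            if len(self.pending) >= required:
                self.global_weights = fedavg(
                    list(self.pending.values()), weighting=self.weighting
                )
                self.pending.clear()
                self.round_index += 1
                self.aggregations += 1
            return {"status": "accepted", "round": self.round_index}


class LoopbackTransport:
    """In-process transport; weights still cross the canonical encoding so
    simulated and networked runs see byte-identical payloads."""

    def __init__(self, server: FederationServer):
        self.server = server

    def get_round(self) -> int:
        return self.server.get_round()

    def get_weight(self) -> dict:
        return decode_payload(encode_payload(self.server.get_weight()))

    def put_weight(self, client_id, round_index, payload, n_k) -> dict:
        payload = decode_payload(encode_payload(payload))
        return self.server.put_weight(client_id, round_index, payload, n_k)


class HttpTransport:
    """Wire transport over the stdlib HTTP client, with bounded retries."""

    def __init__(self, base_url: str, retries: int = 5, backoff: float = 0.1):
        self.base_url = base_url.rstrip("/")
        self.retries = retries
        self.backoff = backoff

    def _call(self, method: str, path: str, body: bytes | None = None) -> dict:
        req = urlrequest.Request(
            self.base_url + path,
            data=body,
            method=method,
            headers={"Content-Type": "application/json"} if body else {},
        )
        last_exc: Exception | None = None
        for attempt in range(self.retries):
            try:
                with urlrequest.urlopen(req, timeout=30) as resp:
                    return json.loads(resp.read().decode())
            except urlerror.HTTPError as exc:
                # 4xx carry a JSON status body per the contract
                try:
                    return json.loads(exc.read().decode())
                except Exception:
                    raise ProtocolError(f"{method} {path}: HTTP {exc.code}") from exc
            except (urlerror.URLError, ConnectionError, TimeoutError) as exc:
                last_exc = exc
                time.sleep(self.backoff * (2**attempt))
        raise ProtocolError(f"{method} {path} failed after {self.retries} retries") from last_exc

    def get_round(self) -> int:
        return int(self._call("GET", "/round")["round"])

    def get_weight(self) -> dict:
        return self._call("GET", "/weight")

    def put_weight(self, client_id, round_index, payload, n_k) -> dict:
        body = encode_payload(
            {
                "client_id": client_id,
                "round_index": round_index,
                "n_k": n_k,
                "weights": payload,
            }
        )
        return self._call("PUT", "/weight", body)


def _make_handler(server: FederationServer):
    class Handler(BaseHTTPRequestHandler):
        def _send(self, code: int, doc: dict) -> None:
            data = json.dumps(doc, sort_keys=True).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def do_GET(self):  # noqa: N802 (stdlib API)
            if self.path == "/round":
                self._send(200, {"round": server.get_round()})
            elif self.path == "/weight":
                try:
                    self._send(200, server.get_weight())
                except ProtocolError as exc:
                    self._send(409, {"status": "uninitialized", "detail": str(exc)})
            else:
                self._send(404, {"status": "not_found"})

        def do_PUT(self):  # noqa: N802
            if self.path != "/weight":
                self._send(404, {"status": "not_found"})
                return
            length = int(self.headers.get("Content-Length", "0"))
            try:
                doc = json.loads(self.rfile.read(length).decode())
                result = server.put_weight(
                    doc["client_id"], doc["round_index"], doc["weights"], doc["n_k"]
                )
            except (KeyError, ValueError, TypeError) as exc:
                self._send(400, {"status": "invalid_payload", "detail": str(exc)})
                return
            self._send(200 if result["status"] == "accepted" else 409, result)

        def log_message(self, *args):  # keep test output quiet
            pass

    return Handler


@contextmanager
def http_server(server: FederationServer, host: str = "127.0.0.1", port: int = 0):
    """Serve the three-call API on a background thread; yields the base URL."""
    httpd = ThreadingHTTPServer((host, port), _make_handler(server))
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    try:
        yield f"http://{httpd.server_address[0]}:{httpd.server_address[1]}"
    finally:
        httpd.shutdown()
        httpd.server_close()
        thread.join(timeout=5)


def participation_loop(
    transport,
    client_id: str,
    records,
    labels,
    spec: ModelSpec,
    cfg: TrainingConfig,
    poll_interval: float = 0.005,
) -> list[int]:
    """Client main loop: poll the round, train when a new one opens, upload.

    Returns the list of round indices in which this client's upload was
    accepted. Terminates when the server's announced round reaches the
    configured round budget.
    """
    labels = np.asarray(labels)
    n_k = len(records)
    accepted: list[int] = []
    last_participated = -1
    while True:
        rnd = transport.get_round()
        if rnd >= cfg.max_rounds:
            return accepted
        if rnd == last_participated:  # already submitted; wait for next round
            time.sleep(poll_interval)
            continue
        payload = transport.get_weight()
        w = WeightSet.from_payload(payload)
        trained = local_train(
            spec, w, records, labels, cfg, seed=client_seed(cfg.seed, rnd, client_id)
        )
        result = transport.put_weight(client_id, rnd, trained.to_payload(), n_k)
        if result["status"] == "accepted":
            accepted.append(rnd)
            last_participated = rnd
        elif result["status"] in ("already_participated", "stale_round"):
            last_participated = max(last_participated, rnd)
            time.sleep(poll_interval)
        elif result["status"] == "finished":
            return accepted
        else:
            raise ProtocolError(f"client {client_id}: server said {result}")
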