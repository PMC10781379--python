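"""Server discovery over UDP and event delivery over TCP.

The server announces itself by broadcasting small JSON datagrams
(``{"service": "thermocough", "ip": ..., "port": ...}``); a device listens on
the announcement port, takes the first valid announcement, and from then on
sends newline-delimited UTF-8 JSON event packets to the announced TCP
endpoint.  The server acknowledges each packet with ``{"ack": <id>}``.
A threaded loopback :class:`MockServer` implements both sides for tests,
examples and the CLI.
"""

from __future__ import annotations

import json
import logging
import socket
import threading
import time
from dataclasses import dataclass

from .packets import EventPacket

log = logging.getLogger(__name__)

DEFAULT_UDP_PORT = 5005
SERVICE_NAME = "thermocough"


class DiscoveryTimeout(RuntimeError):
    """No valid server announcement arrived within the timeout."""


class TransportError(RuntimeError):
    """TCP delivery failed (connection refused, reset, or bad ack)."""


@dataclass(frozen=True)
class ServerEndpoint:
    ip: str
    port: int
    discovered_at: float = 0.0

    def __post_init__(self) -> None:
        socket.inet_aton(self.ip)  # raises OSError on malformed address
        if not (1 <= self.port <= 65535):
            raise ValueError(f"invalid port {self.port}")


def parse_announcement(payload: bytes) -> ServerEndpoint | None:
    """Decode one announcement datagram; None if malformed or foreign."""
    try:
        msg = json.loads(payload.decode("utf-8"))
        if msg.get("service") != SERVICE_NAME:
            return None
        return ServerEndpoint(ip=str(msg["ip"]), port=int(msg["port"]),
                              discovered_at=time.time())
    except (ValueError, KeyError, OSError, UnicodeDecodeError):
        return None


def discover_server(udp_port: int = DEFAULT_UDP_PORT,
                    timeout: float = 5.0) -> ServerEndpoint:
    """Listen for announcements; first valid one wins.

    Malformed datagrams are ignored and listening continues until the
    timeout, after which :class:`DiscoveryTimeout` is raised.
    """
    deadline = time.monotonic() + timeout
    with socket.socket(socket.AF_INET, socket.SOCK_DGRAM) as sock:
        sock.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        sock.bind(("", udp_port))
        while True:
            remaining = deadline - time.monotonic()
            if remaining <= 0:
                raise DiscoveryTimeout(
                    f"no announcement on UDP port {udp_port} "
                    f"within {timeout} s")
            sock.settimeout(remaining)
            try:
                payload, _addr = sock.recvfrom(4096)
            except socket.timeout:
                raise DiscoveryTimeout(
                    f"no announcement on UDP port {udp_port} "
                    f"within {timeout} s") from None
            endpoint = parse_announcement(payload)
            if endpoint is not None:
                log.info("discovered server at %s:%d", endpoint.ip,
                         endpoint.port)
                return endpoint
            log.debug("ignoring malformed announcement")


def send_event(endpoint: ServerEndpoint, packet: EventPacket,
               timeout: float = 5.0, expect_ack: bool = True) -> str | None:
    """Deliver one packet as newline-delimited UTF-8 JSON over TCP.

    Returns the acknowledged packet id (when ``expect_ack``).  Connection
    failures raise :class:`TransportError` with context; they do not crash
    the caller.
    """
    line = (packet.to_json() + "\n").encode("utf-8")
    try:
        with socket.create_connection((endpoint.ip, endpoint.port),
                                      timeout=timeout) as sock:
            sock.sendall(line)
            if not expect_ack:
                return None
            reader = sock.makefile("r", encoding="utf-8")
            ack_line = reader.readline()
        ack = json.loads(ack_line)
        if ack.get("ack") != packet.id:
            raise TransportError(
                f"server acknowledged {ack.get('ack')!r}, sent {packet.id!r}")
        return packet.id
    except OSError as exc:
        raise TransportError(
            f"delivery to {endpoint.ip}:{endpoint.port} failed: {exc}") from exc


class MockServer:
    """Loopback server: TCP packet sink plus UDP announcer, for testing.

    Received packets (parsed dicts, in arrival order) accumulate in
    ``received``.  Use as a context manager::

        with MockServer() as server:
            endpoint = discover_server(server.udp_port, timeout=2)
            send_event(endpoint, packet)
    """

    def __init__(self, host: str = "127.0.0.1", tcp_port: int = 0,
                 udp_port: int = 0, announce_interval: float = 0.1):
        self.host = host
        self.announce_interval = announce_interval
        self.received: list[dict] = []
        self._lock = threading.Lock()
        self._stop = threading.Event()
        self._threads: list[threading.Thread] = []

        self._tcp = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._tcp.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._tcp.bind((host, tcp_port))
        self._tcp.listen(16)
        self.tcp_port = self._tcp.getsockname()[1]

        self._udp = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        if udp_port == 0:
            probe = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
            probe.bind((host, 0))
            udp_port = probe.getsockname()[1]
            probe.close()
        self.udp_port = udp_port

    # -- lifecycle --------------------------------------------------------

    def start(self) -> "MockServer":
        self._tcp.settimeout(0.1)
        t_acc = threading.Thread(target=self._accept_loop, daemon=True)
        t_ann = threading.Thread(target=self._announce_loop, daemon=True)
        self._threads = [t_acc, t_ann]
        for t in self._threads:
            t.start()
        return self

    def stop(self) -> None:
        self._stop.set()
        for t in self._threads:
            t.join(timeout=2.0)
        self._tcp.close()
        self._udp.close()

    def __enter__(self) -> "MockServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    # -- internals --------------------------------------------------------

    def _announce_loop(self) -> None:
        msg = json.dumps({"service": SERVICE_NAME, "ip": self.host,
                          "port": self.tcp_port}).encode("utf-8")
        while not self._stop.is_set():
            try:
                self._udp.sendto(msg, (self.host, self.udp_port))
            except OSError:
                break
            self._stop.wait(self.announce_interval)

    def _accept_loop(self) -> None:
        while not self._stop.is_set():
            try:
                conn, _addr = self._tcp.accept()
            except socket.timeout:
                continue
            except OSError:
                break
            with conn:
                reader = conn.makefile("r", encoding="utf-8")
                for line in reader:
                    line = line.strip()
                    if not line:
                        continue
                    try:
                        obj = json.loads(line)
                    except ValueError:
                        log.warning("mock server: unparseable line")
                        continue
                    with self._lock:
                        self.received.append(obj)
                    ack = json.dumps({"ack": obj.get("id")}) + "\n"
                    try:
                        conn.sendall(ack.encode("utf-8"))
                    except OSError:
                        break

    def snapshot(self) -> list[dict]:
        with self._lock:
            return list(self.received)
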