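"""JSON event packets: device identity, fever rule, base64 audio payload.

A packet is a flat JSON object with keys in fixed order — ``id``, ``time``,
``type`` and exactly one payload field (``temperature`` for thermal events,
``audio`` for cough events).  All keys are lowercase by convention.  Thermal
packets are emitted only when the corrected patient temperature is strictly
above the fever threshold (38.0 degrees C by default).
"""

from __future__ import annotations

import base64
import io
import json
import math
import re
from dataclasses import dataclass
from importlib import resources

from ..audio.frontend import AudioClip, write_wav

FEVER_THRESHOLD_C = 38.0
#: Largest accepted base64 audio payload (characters); a 2 s clip is ~86 kB.
MAX_AUDIO_B64_CHARS = 200_000


class MalformedMAC(ValueError):
    pass


class OversizeAudio(ValueError):
    pass


@dataclass(frozen=True)
class DeviceIdentity:
    """Identity string built from a common name and the MAC address.

    ``id`` is the common name joined with the last four hex digits of the
    MAC, uppercase, e.g. name "E" + MAC ...:12:34 -> "E-1234".
    """

    common_name: str
    mac: bytes

    @property
    def id(self) -> str:
        return f"{self.common_name}-{self.mac[-2:].hex().upper()}"


def make_device_id(common_name: str, mac: str | bytes) -> DeviceIdentity:
    """Parse a MAC in any common textual form and build the identity.

    Accepts ``AA:BB:CC:DD:EE:FF``, ``aa-bb-cc-dd-ee-ff``, bare 12-digit hex,
    or 6 raw bytes; case-insensitive.
    """
    if isinstance(mac, (bytes, bytearray)):
        raw = bytes(mac)
    else:
        digits = re.sub(r"[:\-\.\s]", "", mac)
        if not re.fullmatch(r"[0-9a-fA-F]{12}", digits):
            raise MalformedMAC(f"not a MAC address: {mac!r}")
        raw = bytes.fromhex(digits)
    if len(raw) != 6:
        raise MalformedMAC("MAC must be 6 bytes")
    if not common_name:
        raise ValueError("common name must be non-empty")
    return DeviceIdentity(common_name=common_name, mac=raw)


@dataclass
class EventPacket:
    """One telemetry record; exactly one of temperature/audio is set."""

    id: str
    time: int
    type: str
    temperature: float | None = None
    audio: str | None = None

    def __post_init__(self) -> None:
        if self.type not in ("thermal", "cough"):
            raise ValueError(f"unknown packet type {self.type!r}")
        if self.time < 0:
            raise ValueError("time must be non-negative epoch seconds")
        has_temp = self.temperature is not None
        has_audio = self.audio is not None
        if self.type == "thermal" and not (has_temp and not has_audio):
            raise ValueError("thermal packet needs temperature only")
        if self.type == "cough" and not (has_audio and not has_temp):
            raise ValueError("cough packet needs audio only")

    def to_dict(self) -> dict:
        d = {"id": self.id, "time": int(self.time), "type": self.type}
        if self.temperature is not None:
            d["temperature"] = self.temperature
        if self.audio is not None:
            d["audio"] = self.audio
        return d

    def to_json(self) -> str:
        # Insertion order fixes the byte-exact key order: id, time, type, payload.
        return json.dumps(self.to_dict(), separators=(", ", ": "))

    @classmethod
    def from_json(cls, text: str) -> "EventPacket":
        d = json.loads(text)
        return cls(id=d["id"], time=d["time"], type=d["type"],
                   temperature=d.get("temperature"), audio=d.get("audio"))


def build_thermal_event(identity: DeviceIdentity, corrected_temp: float,
                        time_s: int,
                        threshold: float = FEVER_THRESHOLD_C
                        ) -> EventPacket | None:
    """Fever rule: emit a packet iff the temperature is strictly above the
    threshold; at or below it, nothing is sent."""
    if not math.isfinite(corrected_temp):
        raise ValueError("corrected temperature must be finite")
    if corrected_temp <= threshold:
        return None
    return EventPacket(id=identity.id, time=int(time_s), type="thermal",
                       temperature=float(corrected_temp))


def clip_to_wav_bytes(clip: AudioClip) -> bytes:
    buf = io.BytesIO()
    write_wav(buf, clip)
    return buf.getvalue()


def build_cough_event(identity: DeviceIdentity, clip: AudioClip,
                      time_s: int) -> EventPacket:
    """Cough packet with the clip's WAV bytes base64-encoded in ``audio``."""
    b64 = base64.b64encode(clip_to_wav_bytes(clip)).decode("ascii")
    if len(b64) > MAX_AUDIO_B64_CHARS:
        raise OversizeAudio(
            f"audio payload {len(b64)} chars exceeds {MAX_AUDIO_B64_CHARS}")
    return EventPacket(id=identity.id, time=int(time_s), type="cough",
                       audio=b64)


def decode_cough_audio(packet: EventPacket) -> bytes:
    """WAV bytes carried by a cough packet (inverse of build_cough_event)."""
    if packet.type != "cough" or packet.audio is None:
        raise ValueError("not a cough packet")
    return base64.b64decode(packet.audio)


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

def load_schema() -> dict:
    """The bundled JSON schema describing the packet wire format."""
    ref = resources.files("thermocough.schemas") / "event_packet.schema.json"
    return json.loads(ref.read_text())


def validate_packet(obj: dict, schema: dict | None = None) -> None:
    """Check a decoded packet dict against the bundled schema.

    Minimal validator covering the subset of JSON Schema the bundled file
    uses: required keys, primitive types, enum, pattern, minimum, the
    thermal/cough oneOf payload rule, and additionalProperties.  Raises
    ``ValueError`` on the first violation.
    """
    schema = schema or load_schema()
    props = schema["properties"]
    for key in schema["required"]:
        if key not in obj:
            raise ValueError(f"missing required key {key!r}")
    for key, value in obj.items():
        if key not in props:
            raise ValueError(f"unexpected key {key!r}")
        spec = props[key]
        if "enum" in spec and value not in spec["enum"]:
            raise ValueError(f"{key}={value!r} not in {spec['enum']}")
        expected = spec.get("type")
        if expected == "string" and not isinstance(value, str):
            raise ValueError(f"{key} must be a string")
        if expected == "integer" and not isinstance(value, int):
            raise ValueError(f"{key} must be an integer")
        if expected == "number" and not isinstance(value, (int, float)):
            raise ValueError(f"{key} must be a number")
        if "pattern" in spec and not re.fullmatch(spec["pattern"], value):
            raise ValueError(f"{key}={value!r} fails pattern {spec['pattern']}")
        if "minimum" in spec and value < spec["minimum"]:
            raise ValueError(f"{key}={value} below minimum {spec['minimum']}")
    matches = 0
    for branch in schema["oneOf"]:
        const = branch["properties"]["type"]["const"]
        needed = branch["required"]
        banned = branch["not"]["required"]
        if obj.get("type") == const:
            if all(k in obj for k in needed) and not any(k in obj for k in banned):
                matches += 1
    if matches != 1:
        raise ValueError("packet does not satisfy exactly one payload rule")
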