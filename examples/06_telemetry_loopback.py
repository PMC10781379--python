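"""Device-to-server telemetry on loopback: discovery, JSON packets, acks.

Starts the mock server (UDP announcer + TCP sink), discovers it the way a
device would, and sends one fever packet and one cough packet with its
base64-encoded audio.
"""

from thermocough.audio.synth import synth_clip
from thermocough.telemetry import (
    MockServer,
    build_cough_event,
    build_thermal_event,
    discover_server,
    make_device_id,
    send_event,
)

identity = make_device_id("E", "00:11:22:33:12:34")
print(f"device id: {identity.id} (common name + last four MAC hex digits)")

with MockServer() as server:
    endpoint = discover_server(server.udp_port, timeout=3.0)
    print(f"discovered server at {endpoint.ip}:{endpoint.port} via UDP")

    fever = build_thermal_event(identity, 38.6, time_s=1700000000)
    send_event(endpoint, fever)
    print(f"sent: {fever.to_json()}")

    cough = build_cough_event(identity, synth_clip("cough", 5),
                              time_s=1700000001)
    send_event(endpoint, cough)
    print(f"sent cough packet with {len(cough.audio)} base64 chars of audio")

    import time
    time.sleep(0.2)
    received = server.snapshot()

print(f"server received {len(received)} packets; first matches sent: "
      f"{received[0] == fever.to_dict()}")
print("A 38.0 C reading would produce no packet at all: the fever rule is "
      "strictly above 38 C.")
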