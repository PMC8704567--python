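"""Forward simulation of the two-night stepping-stone migration.

Launches a moth from the scenario's source island at the nominal dusk
take-off and follows the flight rules: land by dawn over land, extend over
sea until landfall (at most 36 h), rest a day, relaunch at the next dusk.
"""

import windborne as wb
from windborne.flight import next_local_clock

field, truth, mask = wb.make_monsoon_scenario(seed=1, leg_count=2)
params = wb.FlightParams()

leg1 = wb.run_leg(wb.ReleaseSpec(*truth.source_centroid, truth.takeoff_time,
                                 1000.0, "forward"), field, mask, params)
print(f"night 1: {leg1.flight_duration_h:.1f} h, landed at "
      f"({leg1.endpoint.lon:.3f}, {leg1.endpoint.lat:.3f}) "
      f"[{leg1.termination_reason}]")

relaunch = next_local_clock(leg1.endpoint.time, leg1.endpoint.lon,
                            params.takeoff_local)
leg2 = wb.run_leg(wb.ReleaseSpec(leg1.endpoint.lon, leg1.endpoint.lat,
                                 relaunch, 1000.0, "forward"), field, mask, params)
err = wb.haversine_km(*truth.expected_arrival_site,
                      leg2.endpoint.lon, leg2.endpoint.lat)
print(f"night 2-3: {leg2.flight_duration_h:.1f} h over-sea crossing, landed "
      f"{err:.1f} km from the trap site [{leg2.termination_reason}]")
print("-> the first night ends at dawn on the stopover island; the second "
      "flight extends past dawn over the sea (dawn-extension rule) and makes "
      "landfall on the arrival landmass during the expected arrival night.")
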