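"""Forecast tomorrow's THI and pedestrian counts from six days of history.

Fits seasonal ARIMA models (daily season, hourly bins) to the first six
days of a synthetic week and predicts the final 24 hours with 95 %
intervals; the collective-exposure forecast is the product of the two.
"""

import pandas as pd

from heattwin import (
    CountGenConfig,
    CountSeries,
    MeteoGenConfig,
    SarimaOrder,
    exposure_table,
    fit_sarima,
    forecast,
    forecast_cthi,
    forecast_counts,
    gen_counts,
    gen_meteo,
    resample_meteo,
)

H = pd.Timedelta(hours=1)
meteo = resample_meteo(gen_meteo(MeteoGenConfig(location_id="11th"), 7, seed=5), H)
counts = gen_counts(CountGenConfig(location_id="11th"), 7, seed=5)
table = exposure_table(meteo, counts)
train = table.iloc[:-24]  # hold out the final day

thi_model = fit_sarima(train["thi"], SarimaOrder(1, 0, 0, 0, 1, 1, 24))
thi_fc = forecast(thi_model, h=24)
cnt_fc = forecast_counts(
    CountSeries("11th", H, train["count"]), SarimaOrder(1, 0, 1, 0, 1, 1, 24), h=24
)
cthi_fc = forecast_cthi(thi_fc, cnt_fc)

print(f"THI model {thi_fc.order}, training R^2 = {thi_fc.training_r2:.3f}")
print(f"count model {cnt_fc.order}, training R^2 = {cnt_fc.training_r2:.3f}")
frame = cthi_fc.to_frame().round(0)
print(frame.iloc[10:16])
truth = table["cthi"].iloc[-24:]
mae = (cthi_fc.point - truth.to_numpy()).__abs__().mean()
print(f"held-out day CTHI MAE: {mae:.0f} person-degF")
# point is the predicted CTHI per hour; lower/upper are the products of
# the 95% bounds of the two component forecasts.
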