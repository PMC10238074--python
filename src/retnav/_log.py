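import logging


def get_logger(name: str) -> logging.Logger:
    logger = logging.getLogger(f"retnav.{name}")
    return logger
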